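"""Slice binarization and data-driven strategy selection.

Micro-CT slices of a polymer foam are bright where there is material and dark
in the air-filled pores, but shading, noise and filler particles make a single
global threshold unreliable. This module wraps local (Niblack, Sauvola) and
global (Otsu, mean, fixed) thresholding behind one polarity-aware surface and
ranks candidate segmentations by the normalized cross-correlation of their
Fourier phase spectra against the original grayscale slice: the phase carries
the edge/structure layout, so the candidate whose phases correlate best with
the original preserves the pore architecture best.

Thresholding formulas (pore = dark convention, ``invert=False``):

* Niblack:  T = m + k * s           (local mean m, local sd s; k defaults to -0.2)
* Sauvola:  T = m * (1 + k * (s/R - 1))   (k = 0.2, R = half the dynamic range)

A pixel strictly below T is pore (1); ``invert=True`` flips the comparison
for bright-pore data. Local windows use reflect padding at the edges. All
operations here are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.filters import threshold_niblack, threshold_otsu, threshold_sauvola

# Tie-break priority when phase-NCC scores are equal: later wins.
METHOD_ORDER = ("fixed", "mean", "otsu", "niblack", "sauvola")


class DegenerateImageError(ValueError):
    """Raised when an image is constant: its Fourier phase spectrum has zero
    variance and the phase correlation is undefined."""


@dataclass
class SegmentationResult:
    """A binary slice (1 = pore), the method that produced it, its parameters
    and, once scored, its Fourier-phase NCC against the source image."""

    binary_image: np.ndarray
    method: str
    parameters: dict = field(default_factory=dict)
    phase_ncc_score: float | None = None


def _check_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D grayscale image, got ndim={img.ndim}")
    return img


def _apply_threshold(image: np.ndarray, t, invert: bool) -> np.ndarray:
    pore = image > t if invert else image < t
    return pore.astype(np.uint8)


def _check_window(image: np.ndarray, window_size: int) -> int:
    window_size = int(window_size)
    if window_size < 3 or window_size % 2 == 0:
        raise ValueError(f"window_size must be odd and >= 3, got {window_size}")
    if window_size > min(image.shape):
        raise ValueError(
            f"window_size {window_size} exceeds image extent {min(image.shape)}"
        )
    return window_size


def niblack_threshold(
    image: np.ndarray,
    window_size: int = 25,
    k: float = -0.2,
    invert: bool = False,
) -> np.ndarray:
    """Local threshold T = mean + k * sd over an odd square window."""
    img = _check_image(image)
    window_size = _check_window(img, window_size)
    # skimage parameterizes Niblack as T = m - k*s; our k enters as m + k*s.
    t = threshold_niblack(img, window_size=window_size, k=-k)
    return _apply_threshold(img, t, invert)


def sauvola_threshold(
    image: np.ndarray,
    window_size: int = 25,
    k: float = 0.2,
    R: float | None = None,
    invert: bool = False,
) -> np.ndarray:
    """Local threshold T = mean * (1 + k * (sd/R - 1)); R defaults to half the
    image's dynamic range."""
    img = _check_image(image)
    window_size = _check_window(img, window_size)
    if R is None:
        R = float(img.max() - img.min()) / 2.0
    if R <= 0:
        raise ValueError(f"R must be positive, got {R}")
    t = threshold_sauvola(img, window_size=window_size, k=k, r=R)
    return _apply_threshold(img, t, invert)


def global_threshold(
    image: np.ndarray,
    method: str = "otsu",
    value: float | None = None,
    invert: bool = False,
) -> np.ndarray:
    """Single image-wide threshold: ``otsu``, ``mean`` or ``fixed`` (with
    ``value``). A fixed threshold outside the intensity range warns and yields
    a degenerate one-class image."""
    import warnings

    img = _check_image(image)
    if method == "otsu":
        t = threshold_otsu(img)
    elif method == "mean":
        t = float(img.mean())
    elif method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding requires a value")
        t = float(value)
        if t < img.min() or t > img.max():
            warnings.warn(
                f"fixed threshold {t} outside intensity range "
                f"[{img.min()}, {img.max()}]: one-class output",
                stacklevel=2,
            )
    else:
        raise ValueError(f"unknown global method {method!r}")
    return _apply_threshold(img, t, invert)


def segment(image: np.ndarray, method: str, **params) -> SegmentationResult:
    """Dispatch a single thresholding method by name."""
    if method == "niblack":
        binary = niblack_threshold(image, **params)
    elif method == "sauvola":
        binary = sauvola_threshold(image, **params)
    elif method in ("otsu", "mean", "fixed"):
        binary = global_threshold(image, method=method, **params)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    return SegmentationResult(binary_image=binary, method=method, parameters=dict(params))


def fourier_phase_ncc(original_image: np.ndarray, binary_image: np.ndarray) -> float:
    """Zero-lag Pearson correlation between the wrapped Fourier phase arrays
    of the grayscale slice and a candidate binary slice, DC term excluded.

    Phase is invariant to positive linear rescaling of intensities, so the
    score compares structure, not contrast. Raises
    :class:`DegenerateImageError` for constant inputs.
    """
    orig = _check_image(original_image)
    cand = np.asarray(binary_image, dtype=np.float64)
    if cand.shape != orig.shape:
        raise ValueError(f"shape mismatch: {orig.shape} vs {cand.shape}")
    for name, img in (("original", orig), ("candidate", cand)):
        if np.ptp(img) == 0:
            raise DegenerateImageError(f"{name} image is constant; phase undefined")
    ph1 = np.angle(np.fft.fft2(orig)).ravel()[1:]  # index 0 is the DC term
    ph2 = np.angle(np.fft.fft2(cand)).ravel()[1:]
    sd1, sd2 = ph1.std(), ph2.std()
    if sd1 == 0 or sd2 == 0:
        raise DegenerateImageError("phase spectrum has zero variance")
    score = float(np.mean((ph1 - ph1.mean()) * (ph2 - ph2.mean())) / (sd1 * sd2))
    return float(np.clip(score, -1.0, 1.0))


def score_segmentation(
    original_image: np.ndarray, binary_image: np.ndarray, invert: bool = False
) -> float:
    """Phase-NCC score of a pore mask against its source slice.

    The pore mask (1 = pore) is first rendered in the source's intensity
    polarity — for pore-dark data the solid phase ``1 - mask`` is the bright
    one — since an intensity inversion shifts every non-DC Fourier phase by
    pi and would penalize a perfect segmentation.
    """
    binary = np.asarray(binary_image)
    seg_img = binary if invert else 1 - binary
    return fourier_phase_ncc(original_image, seg_img)


def default_candidates(
    window_size: int = 25,
    k_niblack: float = -0.2,
    k_sauvola: float = 0.2,
    R: float | None = None,
    invert: bool = False,
) -> list[tuple[str, dict]]:
    """The candidate set scored by automatic selection: Otsu, Niblack, Sauvola."""
    return [
        ("otsu", {"invert": invert}),
        ("niblack", {"window_size": window_size, "k": k_niblack, "invert": invert}),
        ("sauvola", {"window_size": window_size, "k": k_sauvola, "R": R, "invert": invert}),
    ]


def select_segmentation(
    image: np.ndarray,
    candidates: Sequence[tuple[str, dict]] | None = None,
) -> SegmentationResult:
    """Score every candidate with the Fourier-phase NCC and return the argmax.

    Exact score ties are broken by a fixed method ordering
    (fixed < mean < otsu < niblack < sauvola, later preferred). If every
    candidate is degenerate the failures are collected into one error.
    """
    if candidates is None:
        candidates = default_candidates()
    if len(candidates) == 0:
        raise ValueError("candidate set must be nonempty")
    best: SegmentationResult | None = None
    failures: list[str] = []
    for method, params in candidates:
        try:
            result = segment(image, method, **params)
            result.phase_ncc_score = score_segmentation(
                image, result.binary_image, invert=params.get("invert", False)
            )
        except DegenerateImageError as exc:
            failures.append(f"{method}: {exc}")
            continue
        if best is None:
            best = result
            continue
        better = result.phase_ncc_score > best.phase_ncc_score or (
            result.phase_ncc_score == best.phase_ncc_score
            and METHOD_ORDER.index(result.method) > METHOD_ORDER.index(best.method)
        )
        if better:
            best = result
    if best is None:
        raise DegenerateImageError(
            "all candidates degenerate: " + "; ".join(failures)
        )
    return best


def segment_stack(
    stack: np.ndarray,
    method: str = "auto",
    candidates: Sequence[tuple[str, dict]] | None = None,
    **params,
) -> list[SegmentationResult]:
    """Segment each slice of a (n, H, W) grayscale stack.

    ``method='auto'`` runs phase-NCC selection per slice; otherwise the named
    method is applied with ``params`` and scored afterwards.
    """
    results = []
    for img in np.asarray(stack):
        if method == "auto":
            results.append(select_segmentation(img, candidates))
        else:
            res = segment(img, method, **params)
            try:
                res.phase_ncc_score = score_segmentation(
                    img, res.binary_image, invert=params.get("invert", False)
                )
            except DegenerateImageError:
                res.phase_ncc_score = None
            results.append(res)
    return results
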