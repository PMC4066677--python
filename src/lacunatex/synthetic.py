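"""Synthetic porous volumes with known, controllable texture.

Real freeze-dried scaffolds are interconnected foams of roughly spherical
pores whose mean size is an order of magnitude above the imaging resolution.
The generators here emulate the morphologies needed for testing the texture
statistics: exactly periodic lattices (the zero-heterogeneity reference),
i.i.d. Bernoulli fields (the closed-form random reference), overlapping-sphere
foams (the scaffold-like case), and eroded/occluded foams (the analogue of a
filler phase thickening pore walls and occluding micropores). A grayscale
renderer turns any binary volume into a noisy slice stack for segmentation
tests, with the generating volume retained as ground truth.

All randomness is drawn from per-operation ``numpy`` Generators seeded
explicitly: identical parameters and seed give a bit-identical volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volume import BinaryVolume


@dataclass
class SyntheticSpec:
    """Parameters controlling a generated test volume.

    Attributes
    ----------
    dims
        Volume shape (z, y, x); every dimension must be at least 2.
    target_porosity
        Void fraction the generator aims for, strictly inside (0, 1).
    generator
        One of ``regular``, ``bernoulli``, ``foam``, ``occluded_foam``.
    pore_radius_mean, pore_radius_sd
        Truncated-normal sphere radius in voxels (foam generators).
    occlusion_fraction
        Relative pore-volume reduction applied after foam generation
        (``occluded_foam`` only).
    seed
        Non-negative integer; with identical parameters it reproduces the
        volume bit for bit.
    """

    dims: tuple[int, int, int]
    target_porosity: float
    generator: str = "foam"
    pore_radius_mean: float = 7.5
    pore_radius_sd: float = 1.5
    occlusion_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.dims = tuple(int(d) for d in self.dims)  # type: ignore[assignment]
        if len(self.dims) != 3 or any(d < 2 for d in self.dims):
            raise ValueError(f"dims must be a triple of integers >= 2, got {self.dims}")
        if not 0.0 < self.target_porosity < 1.0:
            raise ValueError("target_porosity must lie strictly inside (0, 1)")
        if self.generator not in ("regular", "bernoulli", "foam", "occluded_foam"):
            raise ValueError(f"unknown generator {self.generator!r}")
        if not 0.0 <= self.occlusion_fraction <= 1.0:
            raise ValueError("occlusion_fraction must lie in [0, 1]")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


def regular_lattice(
    dims: Sequence[int],
    period: int,
    pores_per_period: int,
    voxel_size_um: float = 1.0,
) -> BinaryVolume:
    """Exactly periodic volume: every ``period``-sized tile holds the same
    pore pattern (the first ``pores_per_period`` tile positions in C order).

    A periodic volume is the totally regular reference texture: every gliding
    box whose side is a multiple of the period contains the same pore count,
    so the box-count variance — and hence the texture heterogeneity — is zero
    at those scales.
    """
    dims = tuple(int(d) for d in dims)
    period = int(period)
    if period < 1:
        raise ValueError("period must be >= 1")
    for ax, d in enumerate(dims):
        if d % period != 0:
            raise ValueError(f"period {period} does not divide dim {'zyx'[ax]}={d}")
    if not 0 <= pores_per_period <= period**3:
        raise ValueError(f"pores_per_period must lie in [0, {period**3}]")
    tile = np.zeros(period**3, dtype=np.uint8)
    tile[:pores_per_period] = 1
    tile = tile.reshape((period,) * 3)
    reps = tuple(d // period for d in dims)
    vox = np.tile(tile, reps)
    return BinaryVolume(
        vox,
        voxel_size_um=voxel_size_um,
        provenance=f"regular lattice period={period} pores_per_period={pores_per_period}",
    )


def bernoulli_volume(
    dims: Sequence[int], p: float, seed: int, voxel_size_um: float = 1.0
) -> BinaryVolume:
    """i.i.d. random field: each voxel is pore with probability ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    dims = tuple(int(d) for d in dims)
    rng = np.random.default_rng(seed)
    vox = (rng.random(dims) < p).astype(np.uint8)
    return BinaryVolume(
        vox,
        voxel_size_um=voxel_size_um,
        provenance=f"bernoulli p={p} seed={seed}",
    )


def _sphere_offsets(radius: float) -> np.ndarray:
    """Integer offsets of voxels whose centers lie within ``radius`` of the origin."""
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1)
    dz, dy, dx = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = dz**2 + dy**2 + dx**2 <= radius**2
    return np.stack([dz[inside], dy[inside], dx[inside]], axis=1)


def foam_volume(spec: SyntheticSpec, voxel_size_um: float = 1.0) -> BinaryVolume:
    """Overlapping-sphere foam.

    Spheres with truncated-normal radii are carved (voxel centers inside the
    sphere become pore) at uniform random centers until the realized porosity
    first reaches ``target_porosity``; the last sphere may overshoot by its
    own volume. The realized porosity is recorded in the provenance and is an
    exact voxel count.
    """
    if spec.generator not in ("foam", "occluded_foam"):
        raise ValueError("foam_volume requires a foam spec")
    if spec.pore_radius_mean >= min(spec.dims):
        raise ValueError(
            f"pore radius {spec.pore_radius_mean} >= min(dims) {min(spec.dims)}: "
            "target porosity unreachable with resolvable pores"
        )
    rng = np.random.default_rng(spec.seed)
    vox = np.zeros(spec.dims, dtype=np.uint8)
    total = vox.size
    target_count = spec.target_porosity * total
    pore_count = 0
    spheres: list[tuple[int, int, int, float]] = []
    while pore_count < target_count:
        if spec.pore_radius_sd == 0:
            radius = spec.pore_radius_mean
        else:
            radius = -1.0
            while radius < 0.5:  # truncate: a pore must cover its own voxel
                radius = rng.normal(spec.pore_radius_mean, spec.pore_radius_sd)
        center = np.array([rng.integers(0, d) for d in spec.dims])
        pts = center + _sphere_offsets(radius)
        keep = np.all((pts >= 0) & (pts < np.array(spec.dims)), axis=1)
        z, y, x = pts[keep].T
        newly = int(np.count_nonzero(vox[z, y, x] == 0))
        vox[z, y, x] = 1
        pore_count += newly
        spheres.append((int(center[0]), int(center[1]), int(center[2]), float(radius)))
    realized = pore_count / total
    return BinaryVolume(
        vox,
        voxel_size_um=voxel_size_um,
        provenance=(
            f"foam target_porosity={spec.target_porosity} realized={realized:.6f} "
            f"spheres={len(spheres)} radius_mean={spec.pore_radius_mean} "
            f"radius_sd={spec.pore_radius_sd} seed={spec.seed}"
        ),
        metadata={"pore_spheres": spheres, "realized_porosity": realized},
    )


def occlude_pores(
    volume: BinaryVolume, occlusion_fraction: float, seed: int
) -> BinaryVolume:
    """Reduce the pore volume by a relative fraction, emulating a filler
    phase that occludes pores.

    For foam volumes carrying their generating sphere list
    (``metadata['pore_spheres']``), randomly selected whole pores are
    converted to solid — the mechanism of micropore occlusion, which leaves
    the surviving pores at full size and so makes the texture clumpier
    (fewer but larger pores). For arbitrary volumes the pore phase is
    instead eroded shell by shell (6-connected, the array border treated as
    solid). In both modes the final adjustment removes a seeded random
    subset of the current boundary shell, so the output pore count hits
    ``round((1 - f) * V_V)`` exactly; the result is therefore monotone — a
    larger fraction never yields a larger porosity.
    """
    if not 0.0 <= occlusion_fraction <= 1.0:
        raise ValueError("occlusion_fraction must lie in [0, 1]")
    pore_count = int(volume.voxels.sum(dtype=np.int64))
    target = int(round((1.0 - occlusion_fraction) * pore_count))
    rng = np.random.default_rng(seed)
    if "pore_spheres" in volume.metadata:
        vox, pore_count = _remove_whole_pores(volume, target, rng)
    else:
        vox = volume.voxels.copy()
    while pore_count > target:
        pore = vox.astype(bool)
        eroded = ndimage.binary_erosion(pore, border_value=0)
        boundary = np.argwhere(pore & ~eroded)
        need = pore_count - target
        if len(boundary) == 0:
            boundary = np.argwhere(pore)  # isolated voxels only: remove directly
        if len(boundary) <= need:
            z, y, x = boundary.T
            vox[z, y, x] = 0
            pore_count -= len(boundary)
        else:
            pick = boundary[rng.permutation(len(boundary))[:need]]
            z, y, x = pick.T
            vox[z, y, x] = 0
            pore_count -= need
    return BinaryVolume(
        vox,
        voxel_size_um=volume.voxel_size_um,
        provenance=(
            f"{volume.provenance} | occluded fraction={occlusion_fraction} "
            f"seed={seed} realized_porosity={pore_count / vox.size:.6f}"
        ),
    )


def _remove_whole_pores(
    volume: BinaryVolume, target: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Convert randomly selected whole foam spheres to solid while the pore
    count stays above ``target``; overlapping regions survive as long as any
    other sphere still covers them."""
    dims = np.array(volume.dims)
    coverage = np.zeros(volume.dims, dtype=np.int32)
    supports = []
    for cz, cy, cx, radius in volume.metadata["pore_spheres"]:
        pts = np.array([cz, cy, cx]) + _sphere_offsets(radius)
        pts = pts[np.all((pts >= 0) & (pts < dims), axis=1)]
        supports.append(pts)
        coverage[pts[:, 0], pts[:, 1], pts[:, 2]] += 1
    pore_count = int(np.count_nonzero(coverage))
    for idx in rng.permutation(len(supports)):
        pts = supports[idx]
        z, y, x = pts.T
        lost = int(np.count_nonzero(coverage[z, y, x] == 1))
        if pore_count - lost < target:
            continue  # removing this pore would overshoot; try a smaller one
        coverage[z, y, x] -= 1
        pore_count -= lost
        if pore_count == target:
            break
    return (coverage > 0).astype(np.uint8), pore_count


def generate(spec: SyntheticSpec, voxel_size_um: float = 1.0) -> BinaryVolume:
    """Dispatch on ``spec.generator``; ``occluded_foam`` chains foam + occlusion
    (the occlusion stream is seeded with ``spec.seed + 1``)."""
    if spec.generator == "bernoulli":
        return bernoulli_volume(spec.dims, spec.target_porosity, spec.seed, voxel_size_um)
    if spec.generator == "foam":
        return foam_volume(spec, voxel_size_um)
    if spec.generator == "occluded_foam":
        base = foam_volume(spec, voxel_size_um)
        return occlude_pores(base, spec.occlusion_fraction, spec.seed + 1)
    raise ValueError(
        "regular lattices take explicit period/pores_per_period: use regular_lattice()"
    )


def render_grayscale_stack(
    volume: BinaryVolume,
    noise_sd: float = 0.0,
    illumination_gradient: float = 0.0,
    seed: int = 0,
    axis: int = 0,
    solid_value: float = 200.0,
    pore_value: float = 0.0,
) -> np.ndarray:
    """Render a binary volume as a grayscale slice stack.

    Solid maps to a high intensity and pore to a low one (material attenuates
    X-rays more than air), Gaussian noise of standard deviation ``noise_sd``
    is added, and ``illumination_gradient`` adds a linear per-slice ramp of
    that total amplitude along the slice's fast (x) axis. Returns a float64
    array with slices along axis 0; the input volume is the ground truth.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    vox = np.moveaxis(volume.voxels, axis, 0)
    stack = np.where(vox == 1, pore_value, solid_value).astype(np.float64)
    if illumination_gradient != 0.0:
        nx = stack.shape[-1]
        ramp = np.linspace(-0.5, 0.5, nx) * illumination_gradient
        stack = stack + ramp[None, None, :]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
    return stack
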