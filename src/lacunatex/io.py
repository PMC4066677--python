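"""File formats: raw uint8 volumes with JSON sidecar, TIFF stacks, PNG slices."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from .volume import BinaryVolume


def save_raw_volume(volume: BinaryVolume, path: str | Path) -> Path:
    """Write little-endian uint8 voxels in C order (z, y, x) plus a ``.json``
    sidecar with dims and voxel size in micrometres."""
    path = Path(path)
    path.write_bytes(volume.voxels.astype("<u1").tobytes(order="C"))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "dims": list(volume.dims),
                "order": "C (z, y, x)",
                "dtype": "uint8",
                "voxel_size_um": volume.voxel_size_um,
                "provenance": volume.provenance,
            },
            indent=2,
        )
        + "\n"
    )
    return path


def load_raw_volume(path: str | Path) -> BinaryVolume:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar} for raw volume {path}")
    meta = json.loads(sidecar.read_text())
    dims = tuple(meta["dims"])
    vox = np.frombuffer(path.read_bytes(), dtype="<u1").reshape(dims)
    return BinaryVolume(
        vox.copy(),
        voxel_size_um=float(meta.get("voxel_size_um", 1.0)),
        provenance=str(meta.get("provenance", f"loaded from {path.name}")),
    )


def _to_uint(stack: np.ndarray, bit_depth: int) -> np.ndarray:
    if stack.dtype in (np.uint8, np.uint16):
        return stack
    hi = 255 if bit_depth == 8 else 65535
    dt = np.uint8 if bit_depth == 8 else np.uint16
    return np.clip(np.rint(stack), 0, hi).astype(dt)


def write_tiff_stack(
    stack: np.ndarray, path: str | Path, bit_depth: int = 8
) -> Path:
    """Write a (n_slices, H, W) grayscale stack as one multi-page TIFF."""
    path = Path(path)
    tifffile.imwrite(path, _to_uint(np.asarray(stack), bit_depth), photometric="minisblack")
    return path


def write_tiff_slices(
    stack: np.ndarray, directory: str | Path, prefix: str = "slice", bit_depth: int = 8
) -> list[Path]:
    """Write one TIFF file per slice, zero-padded so lexical order is z order."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = _to_uint(np.asarray(stack), bit_depth)
    paths = []
    width = len(str(len(data) - 1))
    for i, img in enumerate(data):
        p = directory / f"{prefix}_{i:0{width}d}.tif"
        tifffile.imwrite(p, img)
        paths.append(p)
    return paths


def read_grayscale_image(path: str | Path) -> np.ndarray:
    """Read a single TIFF/PNG image as 2D float64 (RGB collapsed by channel mean)."""
    img = iio.imread(Path(path))
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    return img


def read_stack(path: str | Path) -> np.ndarray:
    """Read a grayscale stack from a multi-page TIFF file or a directory of
    single-image TIFF/PNG files (sorted by filename)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png")
        )
        if not files:
            raise FileNotFoundError(f"no TIFF/PNG slices in {path}")
        return np.stack([read_grayscale_image(p) for p in files], axis=0)
    data = np.asarray(tifffile.imread(path), dtype=np.float64)
    if data.ndim == 2:
        data = data[None]
    return data
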