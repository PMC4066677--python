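"""Binary pore/solid volumes and geometric operations.

Conventions used throughout the package:

* voxel arrays are C-ordered ``(z, y, x)``, 0-based, with half-open ranges
  for ROI and slab extents;
* voxel value 1 marks pore (void) space and 0 marks solid material;
* physical scale is carried as an isotropic voxel size in micrometres.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

AXIS_INDEX = {"z": 0, "y": 1, "x": 2}


@dataclass(frozen=True)
class PorosityResult:
    """Void volume fraction n = V_V / V_TOT in voxel units."""

    n: float
    pore_voxels: int
    total_voxels: int


@dataclass
class BinaryVolume:
    """A 3D grid of pore (1) / solid (0) voxels with a physical voxel size.

    Parameters
    ----------
    voxels
        3D integer array over {0, 1}; stored as ``uint8`` in C order (z, y, x).
    voxel_size_um
        Isotropic edge length of one voxel, in micrometres. Must be positive.
    provenance
        Free-text note on how the volume was produced.
    metadata
        Optional structured provenance (e.g. a foam generator's pore list);
        not preserved by geometric operations that invalidate it.
    """

    voxels: np.ndarray
    voxel_size_um: float = 1.0
    provenance: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"expected a 3D voxel grid, got ndim={vox.ndim}")
        if vox.size == 0:
            raise ValueError("empty voxel grid")
        if not np.isin(vox, (0, 1)).all():
            raise ValueError("voxel values must be exactly 0 (solid) or 1 (pore)")
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be positive, got {self.voxel_size_um}")
        object.__setattr__(self, "voxels", vox.astype(np.uint8, copy=False))

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]

    @property
    def is_cubic(self) -> bool:
        d = self.dims
        return d[0] == d[1] == d[2]

    def porosity(self) -> PorosityResult:
        return porosity(self)


def porosity(volume: BinaryVolume) -> PorosityResult:
    """Porosity n = V_V / V_TOT by exact voxel count (no estimation)."""
    pore = int(volume.voxels.sum(dtype=np.int64))
    total = int(volume.voxels.size)
    return PorosityResult(n=pore / total, pore_voxels=pore, total_voxels=total)


def stack_to_volume(
    binary_slices: Sequence[np.ndarray],
    voxel_size_um: float = 1.0,
    provenance: str = "stacked slices",
) -> BinaryVolume:
    """Assemble 2D binary slices into a volume; slices become constant-z planes
    in acquisition order."""
    if len(binary_slices) == 0:
        raise ValueError("at least one slice is required")
    shape0 = np.asarray(binary_slices[0]).shape
    for i, s in enumerate(binary_slices):
        if np.asarray(s).shape != shape0:
            raise ValueError(
                f"slice {i} has shape {np.asarray(s).shape}, expected {shape0}"
            )
    vox = np.stack([np.asarray(s) for s in binary_slices], axis=0)
    return BinaryVolume(vox, voxel_size_um=voxel_size_um, provenance=provenance)


def extract_roi(
    volume: BinaryVolume,
    origin: Sequence[int],
    size: Sequence[int],
) -> BinaryVolume:
    """Copy the sub-block ``[origin, origin + size)`` (z, y, x order)."""
    origin = tuple(int(o) for o in origin)
    size = tuple(int(s) for s in size)
    for ax, (o, s, d) in enumerate(zip(origin, size, volume.dims)):
        if o < 0 or s < 1 or o + s > d:
            raise ValueError(
                f"ROI out of bounds on axis {'zyx'[ax]}: origin={o}, size={s}, dim={d}"
            )
    z, y, x = origin
    dz, dy, dx = size
    sub = volume.voxels[z : z + dz, y : y + dy, x : x + dx].copy()
    return BinaryVolume(
        sub,
        voxel_size_um=volume.voxel_size_um,
        provenance=f"{volume.provenance} | ROI origin={origin} size={size}",
    )


@dataclass
class SubvolumeSpec:
    """Parallel slabs cut perpendicular to one axis.

    ``thickness`` may be given in voxels (default) or micrometres; micrometre
    thickness is converted by rounding ``thickness / voxel_size`` to the
    nearest integer, with a minimum of 1 voxel.
    """

    offsets: Sequence[int]
    thickness: float
    axis: str = "z"
    thickness_unit: str = "voxels"

    def __post_init__(self) -> None:
        if self.axis not in AXIS_INDEX:
            raise ValueError(f"axis must be one of {sorted(AXIS_INDEX)}, got {self.axis!r}")
        if self.thickness_unit not in ("voxels", "um"):
            raise ValueError("thickness_unit must be 'voxels' or 'um'")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        if len(self.offsets) == 0:
            raise ValueError("at least one slab offset is required")

    def thickness_voxels(self, voxel_size_um: float) -> int:
        if self.thickness_unit == "voxels":
            return max(1, int(round(self.thickness)))
        t = max(1, int(round(self.thickness / voxel_size_um)))
        logger.info(
            "thickness %.1f um at %.2f um/voxel -> %d voxels (%.1f um realized)",
            self.thickness, voxel_size_um, t, t * voxel_size_um,
        )
        return t


def equispaced_offsets(extent: int, n_slabs: int, thickness_voxels: int) -> list[int]:
    """Evenly spaced, non-overlapping slab start indices along one axis."""
    if n_slabs * thickness_voxels > extent:
        raise ValueError(
            f"{n_slabs} slabs of {thickness_voxels} voxels do not fit in extent {extent}"
        )
    gap = (extent - n_slabs * thickness_voxels) // (n_slabs + 1)
    return [gap + i * (thickness_voxels + gap) for i in range(n_slabs)]


def extract_subvolumes(volume: BinaryVolume, spec: SubvolumeSpec) -> list[BinaryVolume]:
    """Extract parallel slabs in offset order; overlap warns, out-of-bounds rejects."""
    ax = AXIS_INDEX[spec.axis]
    extent = volume.dims[ax]
    t = spec.thickness_voxels(volume.voxel_size_um)
    offsets = [int(o) for o in spec.offsets]
    for o in offsets:
        if o < 0 or o + t > extent:
            raise ValueError(
                f"slab [{o}, {o + t}) out of bounds on axis {spec.axis} (extent {extent})"
            )
    for a, b in zip(sorted(offsets), sorted(offsets)[1:]):
        if b < a + t:
            warnings.warn(f"slabs at offsets {a} and {b} overlap", stacklevel=2)
            break
    slabs = []
    for o in offsets:
        origin = [0, 0, 0]
        size = list(volume.dims)
        origin[ax] = o
        size[ax] = t
        slabs.append(extract_roi(volume, origin, size))
    return slabs


def concatenate_volumes(volumes: Sequence[BinaryVolume], axis: str = "z") -> BinaryVolume:
    """Stack volumes along one axis; cross-sections and voxel sizes must match."""
    ax = AXIS_INDEX[axis]
    if len(volumes) == 0:
        raise ValueError("nothing to concatenate")
    vs = volumes[0].voxel_size_um
    if any(v.voxel_size_um != vs for v in volumes):
        raise ValueError("voxel sizes differ")
    vox = np.concatenate([v.voxels for v in volumes], axis=ax)
    return BinaryVolume(vox, voxel_size_um=vs, provenance="concatenated slabs")
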