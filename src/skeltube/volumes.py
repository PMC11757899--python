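"""Volume containers shared across the package.

All volumes are dense 3D scalar fields indexed ``(z, y, x)`` with an
associated voxel spacing in millimetres.  Connectivity and the
centerline-based metrics operate in index space; spacing is carried only
so that volumes can round-trip through NIfTI with correct geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "Geometry",
    "VoxelGrid",
    "BinaryVolume",
    "LikelihoodVolume",
    "SkeletonVolume",
    "read_nifti",
    "write_nifti",
    "LIKELIHOOD_EPS",
]

#: Likelihoods are clamped to [EPS, 1 - EPS] so that losses and their
#: gradient ratios stay finite.
LIKELIHOOD_EPS = 1e-6


@dataclass(frozen=True)
class Geometry:
    """Grid shape ``(D, H, W)`` plus per-axis voxel spacing in mm."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing_mm}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))


@dataclass
class VoxelGrid:
    """A 3D scalar field (e.g. an image intensity volume)."""

    values: np.ndarray
    geometry: Geometry = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        if self.geometry is None:
            self.geometry = Geometry(self.values.shape)
        elif tuple(self.values.shape) != self.geometry.shape:
            raise ValueError(
                f"array shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.geometry.shape

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        return self.geometry.spacing_mm


class BinaryVolume(VoxelGrid):
    """A strictly binary {0, 1} volume (masks, binarized predictions)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.asarray(self.values)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("BinaryVolume values must be exactly 0 or 1")
        self.values = vals.astype(np.uint8, copy=False)

    def count(self) -> int:
        return int(self.values.sum())


class SkeletonVolume(BinaryVolume):
    """A thin binary volume: no 2x2x2 neighborhood is entirely foreground."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not thinness_holds(self.values):
            raise ValueError("SkeletonVolume violates thinness (a full 2x2x2 block exists)")


class LikelihoodVolume(VoxelGrid):
    """Per-voxel likelihoods clamped to the open interval via LIKELIHOOD_EPS."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(vals).all():
            raise ValueError("likelihoods must be finite")
        if vals.min() < 0.0 or vals.max() > 1.0:
            raise ValueError("likelihoods must lie in [0, 1] before clamping")
        self.values = np.clip(vals, LIKELIHOOD_EPS, 1.0 - LIKELIHOOD_EPS)


def thinness_holds(mask: np.ndarray) -> bool:
    """True iff no 2x2x2 block of ``mask`` is entirely foreground."""
    m = np.asarray(mask, dtype=bool)
    if any(s < 2 for s in m.shape):
        return True
    blocks = (
        m[:-1, :-1, :-1] & m[1:, :-1, :-1] & m[:-1, 1:, :-1] & m[:-1, :-1, 1:]
        & m[1:, 1:, :-1] & m[1:, :-1, 1:] & m[:-1, 1:, 1:] & m[1:, 1:, 1:]
    )
    return not bool(blocks.any())


def _affine(spacing_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def write_nifti(path, volume: VoxelGrid, dtype=None) -> None:
    """Write a volume as NIfTI; spacing goes into the affine/zooms."""
    if dtype is None:
        dtype = np.uint8 if isinstance(volume, BinaryVolume) else np.float32
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=dtype), _affine(volume.spacing_mm))
    nib.save(img, str(path))


def read_nifti(path, kind: type = VoxelGrid) -> VoxelGrid:
    """Read a NIfTI file into the requested volume class."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    geom = Geometry(data.shape, spacing)
    return kind(data, geom)
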