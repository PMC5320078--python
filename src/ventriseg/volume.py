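"""In-memory containers for CT volumes and binary masks.

Arrays are indexed ``[x, y, z]`` (column, row, slice), 0-based.  All geometry
(plane fits, midsagittal lines, morphology radii) lives in this voxel index
space; physical spacing enters only where millimetres are required (boundary
distances, volumes).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CTVolume", "BinaryVolume", "check_same_geometry"]


@dataclass
class CTVolume:
    """A 3D head-CT volume in Hounsfield units.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar field in HU (rescale slope/intercept already applied).
    spacing : tuple of float
        ``(dx, dy, dz)`` voxel spacing in mm.
    affine : ndarray or None
        Optional 4x4 voxel-to-world matrix carried opaquely through I/O.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError(f"CT volume must be 3D, got shape {self.voxels.shape}")
        if self.voxels.shape[2] < 3:
            raise ValueError("CT volume needs at least 3 slices for 3D operations")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def nz(self) -> int:
        return self.voxels.shape[2]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of a single voxel in millilitres."""
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    def warn_if_no_air(self) -> None:
        # A genuine head scan always contains air (about -1000 HU) around the
        # head; a volume with min >= 0 is probably not rescaled to HU.
        if float(self.voxels.min()) >= 0:
            warnings.warn(
                "volume contains no negative HU values; check that the CT "
                "rescale slope/intercept were applied",
                stacklevel=2,
            )


@dataclass
class BinaryVolume:
    """A boolean mask aligned with a :class:`CTVolume`."""

    mask: np.ndarray
    spacing: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.mask.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def count(self) -> int:
        return int(self.mask.sum())

    def volume_ml(self) -> float:
        dx, dy, dz = self.spacing
        return self.count() * dx * dy * dz / 1000.0

    def copy(self) -> "BinaryVolume":
        return BinaryVolume(self.mask.copy(), self.spacing)


def check_same_geometry(mask: BinaryVolume, ref: CTVolume | BinaryVolume) -> None:
    """Raise if ``mask`` does not share ``ref``'s grid shape."""
    ref_shape = ref.shape
    if mask.shape != ref_shape:
        raise ValueError(f"mask shape {mask.shape} does not match volume shape {ref_shape}")
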