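"""Physical calibration and calibrated image containers.

All arrays are ordered (z, y, x).  The physical coordinate of a voxel is
``index * spacing`` in micrometres, with the origin at the centre of the
first voxel.  Topology operations act on the voxel grid; every length,
distance and volume reported by the package is in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHANNELS = ("endothelium", "pericyte", "microglia")


@dataclass(frozen=True)
class VoxelGeometry:
    """Voxel-to-micrometre calibration of a 3D stack.

    Parameters
    ----------
    spacing_zyx : tuple of float
        Physical edge length of a voxel along (z, y, x), in µm.
    shape_zyx : tuple of int
        Number of voxels along (z, y, x).
    """

    spacing_zyx: tuple[float, float, float]
    shape_zyx: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.spacing_zyx) != 3 or len(self.shape_zyx) != 3:
            raise ValueError("spacing_zyx and shape_zyx must have length 3")
        object.__setattr__(self, "spacing_zyx", tuple(float(s) for s in self.spacing_zyx))
        object.__setattr__(self, "shape_zyx", tuple(int(n) for n in self.shape_zyx))
        if any(not np.isfinite(s) or s <= 0 for s in self.spacing_zyx):
            raise ValueError(f"voxel spacings must be strictly positive, got {self.spacing_zyx}")
        if any(n < 1 for n in self.shape_zyx):
            raise ValueError(f"shape entries must be >= 1, got {self.shape_zyx}")

    @property
    def spacing(self) -> np.ndarray:
        return np.asarray(self.spacing_zyx, dtype=float)

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_um3(self) -> float:
        return float(np.prod(self.spacing) * np.prod(self.shape_zyx))

    @property
    def volume_mm3(self) -> float:
        return self.volume_um3 * 1e-9

    def physical_coords(self, indices: np.ndarray) -> np.ndarray:
        """Map voxel indices (N, 3) to physical coordinates in µm."""
        return np.asarray(indices, dtype=float) * self.spacing

    @property
    def planar(self) -> "VoxelGeometry":
        """Geometry of a 2D projection along z (kept 3D with a single plane)."""
        return VoxelGeometry((self.spacing_zyx[0], self.spacing_zyx[1], self.spacing_zyx[2]),
                             (1, self.shape_zyx[1], self.shape_zyx[2]))


@dataclass
class IntensityVolume:
    """A calibrated 3D fluorescence channel.

    values : (z, y, x) float array of finite, non-negative intensities.
    geometry : the voxel calibration.
    channel : one of 'endothelium', 'pericyte', 'microglia' (free labels allowed).
    """

    values: np.ndarray
    geometry: VoxelGeometry
    channel: str = "endothelium"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D (z, y, x), got ndim={self.values.ndim}")
        if tuple(self.values.shape) != self.geometry.shape_zyx:
            raise ValueError(
                f"values shape {self.values.shape} does not match geometry "
                f"shape {self.geometry.shape_zyx}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity values must be finite (no NaN/inf)")
        if np.any(self.values < 0):
            raise ValueError("intensity values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.geometry.shape_zyx


@dataclass
class BinaryVolume:
    """A calibrated 3D boolean mask (e.g. the segmented vessel lumen)."""

    values: np.ndarray
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"mask must be 3D (z, y, x), got ndim={self.values.ndim}")
        if tuple(self.values.shape) != self.geometry.shape_zyx:
            raise ValueError(
                f"mask shape {self.values.shape} does not match geometry "
                f"shape {self.geometry.shape_zyx}")

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_um3(self) -> float:
        return self.voxel_count * self.geometry.voxel_volume_um3
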