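"""Shared voxel containers.

All volumes are indexed ``(z, y, x)`` with an isotropic voxel size in mm.
Voxel centers sit at ``(i + 0.5) * voxel_size`` along each axis, and slab
intervals are half-open (first plane included, end plane excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelVolume", "BinaryMask"]


@dataclass
class VoxelVolume:
    """A 3D grayscale micro-CT volume with isotropic voxel geometry.

    Parameters
    ----------
    data:
        3D array, axis order ``(z, y, x)``.
    voxel_size:
        Edge length of the cubic voxel in mm. Must be positive.
    intensity_units:
        Free-text label for the intensity scale (``"gray"`` for raw detector
        units, ``"HU"`` for water-calibrated Hounsfield units).
    """

    data: np.ndarray
    voxel_size: float
    intensity_units: str = "gray"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all axes must be >= 1, got shape {self.data.shape}")
        if not (float(self.voxel_size) > 0):
            raise ValueError(f"voxel_size must be > 0 mm, got {self.voxel_size}")
        self.voxel_size = float(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of a single voxel in mm^3."""
        return self.voxel_size**3


@dataclass
class BinaryMask:
    """A boolean bone/background mask sharing the geometry of its source volume."""

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.data.ndim}")
        if not (float(self.voxel_size) > 0):
            raise ValueError(f"voxel_size must be > 0 mm, got {self.voxel_size}")
        self.voxel_size = float(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size**3

    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        """Foreground volume in mm^3 (voxel count x voxel volume)."""
        return self.count() * self.voxel_volume_mm3

    def has_margin(self, width: int = 1) -> bool:
        """True when no foreground voxel lies within ``width`` voxels of a face."""
        d = self.data
        w = int(width)
        inner = np.zeros_like(d)
        inner[w:-w or None, w:-w or None, w:-w or None] = d[
            w:-w or None, w:-w or None, w:-w or None
        ]
        return bool((d == inner).all())
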