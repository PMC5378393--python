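"""Phantom-calibrated densitometry: grayscale -> mg-HA/cm^3 and BMD/BMC.

Calibration fits density as an affine function of the per-insert mean
grayscale of a hydroxyapatite step phantom (ordinary least squares with the
known insert densities as the response).  BMD is the mean calibrated density
over the *total tissue volume* — bone and marrow voxels alike — and BMC is
BMD times TV.

Units: BMD in mg-HA/cm^3 and TV in mm^3 give BMC = BMD x TV in units of
1e-3 mg-HA, i.e. micrograms of hydroxyapatite.  BMC is therefore reported in
ug-HA throughout this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .volume import BinaryMask, VoxelVolume

__all__ = [
    "CalibrationModel",
    "DensitometryResult",
    "fit_calibration",
    "insert_mean_grays",
    "compute_bmd_bmc",
]


@dataclass
class CalibrationModel:
    """Affine map from grayscale to mineral density (mg-HA/cm^3 per gray)."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    residuals: np.ndarray | None = None  # per-insert, mg-HA/cm^3

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("calibration needs >= 2 points")
        if not np.isfinite(self.slope) or self.slope == 0:
            raise ValueError(f"calibration slope must be finite and nonzero, got {self.slope}")
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValueError(f"r_squared must lie in [0, 1], got {self.r_squared}")

    def density(self, gray: np.ndarray | float) -> np.ndarray | float:
        """Calibrated density; sub-water voxels are clamped at 0 mg-HA/cm^3."""
        return np.maximum(self.slope * np.asarray(gray, dtype=float) + self.intercept, 0.0)


@dataclass
class DensitometryResult:
    bmd: float  # mg-HA/cm^3 over TV
    bmc: float  # ug-HA (BMD x TV; see module docstring on units)
    total_tissue_volume: float  # mm^3
    tissue_mineral_density: float  # mg-HA/cm^3 over bone voxels only (secondary)


def fit_calibration(
    insert_mean_grays: list[float], insert_densities: list[float]
) -> CalibrationModel:
    """OLS fit of density = slope * gray + intercept.

    Density is the response: the insert densities are manufactured ground
    truth while the grayscale means carry the measurement noise.
    """
    grays = np.asarray(insert_mean_grays, dtype=float)
    densities = np.asarray(insert_densities, dtype=float)
    if grays.shape != densities.shape:
        raise ValueError("gray and density lists must have equal length")
    if grays.size < 2 or np.unique(grays).size < 2:
        raise ValueError("calibration needs >= 2 distinct gray values")
    if grays.size == 2:
        slope = (densities[1] - densities[0]) / (grays[1] - grays[0])
        intercept = densities[0] - slope * grays[0]
        r2 = 1.0
    else:
        fit = sps.linregress(grays, densities)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2 = float(fit.rvalue**2)
    predicted = slope * grays + intercept
    return CalibrationModel(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=min(max(r2, 0.0), 1.0),
        n_points=int(grays.size),
        residuals=densities - predicted,
    )


def insert_mean_grays(volume: VoxelVolume, insert_masks: list[BinaryMask]) -> list[float]:
    """Mean grayscale inside each phantom insert."""
    out = []
    for m in insert_masks:
        if not m.data.any():
            raise ValueError("empty insert mask")
        out.append(float(volume.data[m.data].mean()))
    return out


def compute_bmd_bmc(
    volume: VoxelVolume,
    tv_region: BinaryMask,
    model: CalibrationModel,
    bone_mask: BinaryMask | None = None,
) -> DensitometryResult:
    """BMD over the total tissue volume and the corresponding BMC.

    BMD averages the calibrated density over *all* TV voxels (marrow
    included); BMC = BMD x TV in ug-HA.  When ``bone_mask`` is given, the
    bone-restricted tissue mineral density is reported as a secondary output.
    """
    if volume.data.shape != tv_region.shape:
        raise ValueError("volume and tv_region shapes differ")
    n_tv = tv_region.count()
    if n_tv == 0:
        raise ValueError("empty total-tissue region: BMD undefined")
    density = model.density(volume.data[tv_region.data])
    bmd = float(np.mean(density))
    tv_mm3 = n_tv * tv_region.voxel_volume_mm3
    tmd = float("nan")
    if bone_mask is not None:
        inside = bone_mask.data & tv_region.data
        if inside.any():
            tmd = float(np.mean(model.density(volume.data[inside])))
    return DensitometryResult(
        bmd=bmd,
        bmc=bmd * tv_mm3,
        total_tissue_volume=tv_mm3,
        tissue_mineral_density=tmd,
    )
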