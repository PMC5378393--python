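"""Volume I/O, growth-plate-referenced ROI extraction, and binarization.

Volumes travel as multi-page grayscale TIFF stacks with a plain-text metadata
sidecar (``<stem>.meta``, ``key=value`` lines) carrying ``voxel_size_mm`` and
``axis_order``.  All geometry is isotropic; anisotropic sidecars are rejected
because every downstream quantity is reported in mm and mg-HA.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import tifffile
from skimage.filters import threshold_otsu

from .volume import BinaryMask, VoxelVolume

__all__ = [
    "RoiSpec",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "extract_roi",
    "binarize",
]

_AXIS_ORDER = "z,y,x"


@dataclass
class RoiSpec:
    """Standardized distal-metaphysis ROI relative to the growth plate.

    The reference plane is the z index of the growth plate (located manually or
    taken from synthetic ground truth).  The slab starts ``offset`` mm past the
    reference on the metaphysis side and spans ``extent`` mm; with the study
    defaults (offset 0.5 mm, extent 2.0 mm at 9 um voxels) that is a 222-plane
    slab starting 56 planes past the growth plate.
    """

    reference_plane_index: int
    offset: float = 0.5
    extent: float = 2.0
    direction: str = "+z"

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError(f"offset must be >= 0 mm, got {self.offset}")
        if not (self.extent > 0):
            raise ValueError(f"extent must be > 0 mm, got {self.extent}")
        if self.direction not in ("+z", "-z"):
            raise ValueError(f"direction must be '+z' or '-z', got {self.direction!r}")


def _sidecar_path(path: str) -> str:
    stem, _ = os.path.splitext(path)
    return stem + ".meta"


def write_volume(volume: VoxelVolume, path: str) -> None:
    """Write a multi-page TIFF plus ``.meta`` sidecar; round trip is lossless."""
    tifffile.imwrite(path, volume.data)
    with open(_sidecar_path(path), "w") as fh:
        fh.write(f"voxel_size_mm={volume.voxel_size!r}\n")
        fh.write(f"axis_order={_AXIS_ORDER}\n")
        fh.write(f"intensity_units={volume.intensity_units}\n")


def _read_sidecar(path: str) -> dict[str, str]:
    sidecar = _sidecar_path(path)
    if not os.path.exists(sidecar):
        raise FileNotFoundError(
            f"metadata sidecar {sidecar!r} not found: voxel size is required "
            "(outputs are in mm and mg-HA; unitless volumes are meaningless)"
        )
    meta: dict[str, str] = {}
    with open(sidecar) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            meta[key.strip()] = value.strip()
    return meta


def _voxel_size_from_meta(meta: dict[str, str], path: str) -> float:
    if "voxel_size_mm" not in meta:
        raise KeyError(f"sidecar for {path!r} lacks required key 'voxel_size_mm'")
    parts = [float(p) for p in meta["voxel_size_mm"].strip("()[] ").split(",") if p.strip()]
    if len(parts) > 1 and not np.allclose(parts, parts[0]):
        raise ValueError(
            f"anisotropic voxel size {parts} is unsupported: the morphometry "
            "pipeline assumes isotropic micro-CT geometry"
        )
    return parts[0]


def read_volume(path: str) -> VoxelVolume:
    """Read a TIFF stack written by :func:`write_volume` (or any stack with a
    compatible sidecar)."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    meta = _read_sidecar(path)
    return VoxelVolume(
        data=data,
        voxel_size=_voxel_size_from_meta(meta, path),
        intensity_units=meta.get("intensity_units", "gray"),
    )


def write_mask(mask: BinaryMask, path: str) -> None:
    """Masks are stored as 8-bit TIFF with foreground = 255."""
    tifffile.imwrite(path, (mask.data.astype(np.uint8) * 255))
    with open(_sidecar_path(path), "w") as fh:
        fh.write(f"voxel_size_mm={mask.voxel_size!r}\n")
        fh.write(f"axis_order={_AXIS_ORDER}\n")


def read_mask(path: str) -> BinaryMask:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    meta = _read_sidecar(path)
    return BinaryMask(data=data > 0, voxel_size=_voxel_size_from_meta(meta, path))


def extract_roi(volume: VoxelVolume, spec: RoiSpec) -> VoxelVolume:
    """Extract the metaphyseal slab defined by ``spec``.

    The slab covers ``[reference + offset, reference + offset + extent)`` in mm
    on the metaphysis side; plane counts are rounded to the nearest voxel.  For
    ``direction='-z'`` the volume is mirrored along z first, so the returned
    slab equals the ``+z`` slab of the flipped volume.
    """
    vs = volume.voxel_size
    data = volume.data
    ref = int(spec.reference_plane_index)
    if spec.direction == "-z":
        data = data[::-1]
        ref = data.shape[0] - 1 - ref
    if not (0 <= ref < data.shape[0]):
        raise ValueError(f"reference plane {ref} outside volume of {data.shape[0]} planes")
    n_offset = int(round(spec.offset / vs))
    n_planes = int(round(spec.extent / vs))
    n_planes = max(n_planes, 1)
    start = ref + n_offset
    stop = start + n_planes
    if stop > data.shape[0]:
        shortfall_mm = (stop - data.shape[0]) * vs
        raise ValueError(
            f"ROI slab [{start}, {stop}) exceeds the volume ({data.shape[0]} planes): "
            f"short by {shortfall_mm:.4f} mm"
        )
    return VoxelVolume(
        data=data[start:stop].copy(),
        voxel_size=vs,
        intensity_units=volume.intensity_units,
    )


def binarize(
    volume: VoxelVolume,
    method: str = "otsu",
    threshold: float | None = None,
) -> BinaryMask:
    """Threshold a grayscale ROI into a bone mask.

    ``method='otsu'`` computes the Otsu threshold on a 256-bin histogram over
    the observed intensity range; ``method='fixed'`` requires ``threshold``.
    Foreground is ``intensity >= threshold`` in both cases, so raising a fixed
    threshold always shrinks the mask (monotonicity).
    """
    data = volume.data
    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires an explicit threshold")
        thr = float(threshold)
    elif method == "otsu":
        if np.ptp(data) == 0:
            raise ValueError(
                "constant-intensity volume: Otsu thresholding has no separable classes"
            )
        thr = float(threshold_otsu(data.astype(np.float64), nbins=256))
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return BinaryMask(data=data >= thr, voxel_size=volume.voxel_size)
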