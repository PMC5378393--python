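"""Global (non-graph) morphometric parameters of a binarized trabecular ROI.

Covers total tissue volume (TV), bone volume (BV), percent bone volume
(BV/TV), iso-surface area and the surface-area-to-volume ratio (SA/V),
box-counting fractal dimension (FD), the structure model index (SMI), and the
vertical extent of the trabecular compartment past a reference plane.

Conventions
-----------
* Surfaces are triangulated with marching cubes on the signed Euclidean
  distance field of the mask, corrected by half a voxel so that level 0 is the
  bone/background interface (the 0.5-level of the binary field), and lightly
  smoothed to remove lattice quantization.  Meshing the raw 0/1 field instead
  overestimates smooth surfaces by ~8% (staircase bias).
* SMI follows the differential-surface definition SMI = 6 V S' / S**2 with
  S' the surface-area derivative under a normal offset of the iso-surface,
  estimated by displacing mesh vertices along their normals by half a voxel
  (central difference).  Convex rod/plate/sphere limits are 3 / 0 / 4;
  concave structures may leave [0, 3].
* FD is volume-occupancy box counting on a grid-aligned partition anchored at
  the foreground bounding box (making the estimate translation invariant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area

from .volume import BinaryMask

__all__ = [
    "GlobalMorphometry",
    "compute_volumes",
    "compute_surface_area",
    "box_counts",
    "fractal_dimension",
    "structure_model_index",
    "vertical_length",
    "compute_global_morphometry",
]


@dataclass
class GlobalMorphometry:
    total_tissue_volume: float  # mm^3
    bone_volume: float  # mm^3
    percent_bone_volume: float  # %
    surface_area: float  # mm^2
    sa_to_v: float  # mm^-1
    fractal_dimension: float
    smi: float
    vertical_length: float  # mm


def compute_volumes(mask: BinaryMask, tv_region: BinaryMask) -> tuple[float, float, float]:
    """TV, BV (mm^3) and BV/TV (%) by direct voxel counting.

    TV is the volume of the analysed region (bone and marrow alike); BV the
    bone voxels inside it.
    """
    if mask.shape != tv_region.shape:
        raise ValueError(f"mask shape {mask.shape} != tv_region shape {tv_region.shape}")
    n_tv = tv_region.count()
    if n_tv == 0:
        raise ValueError("empty tv_region: total tissue volume undefined")
    vv = mask.voxel_volume_mm3
    tv = n_tv * vv
    bv = int((mask.data & tv_region.data).sum()) * vv
    return tv, bv, 100.0 * bv / tv


_SURFACE_SMOOTH_SIGMA = 0.6  # voxels; removes EDT lattice quantization


def _signed_distance(mask: np.ndarray, sigma: float = _SURFACE_SMOOTH_SIGMA) -> np.ndarray:
    """Signed distance to the bone surface in voxel units, positive inside.

    The center-to-center EDT is shifted by half a voxel so the zero level sits
    on the bone/background interface, then smoothed to suppress the
    direction-dependent quantization of near-surface distances.
    """
    sd = ndimage.distance_transform_edt(mask) - ndimage.distance_transform_edt(~mask)
    sd = sd - 0.5 * np.sign(sd)
    if sigma > 0:
        sd = ndimage.gaussian_filter(sd, sigma)
    return sd


def _surface_mesh(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Iso-surface mesh of the bone interface: (verts, faces, unit normals)."""
    sd = _signed_distance(mask)
    verts, faces, normals, _ = marching_cubes(sd, level=0.0)
    normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    return verts, faces, normals


def compute_surface_area(mask: BinaryMask, method: str = "mesh") -> float:
    """Bone surface area in mm^2.

    ``mesh`` triangulates the half-voxel iso-surface (default; accurate for
    smooth structures).  ``voxel_faces`` counts exposed voxel faces — an exact
    combinatorial quantity kept as a diagnostic: it overestimates smooth
    surfaces by a bounded orientation-dependent factor (1.5 for a sphere).
    """
    if not mask.data.any():
        raise ValueError("empty mask has no surface")
    if not mask.has_margin(1):
        raise ValueError("mask must have a background margin on all faces")
    vs = mask.voxel_size
    if method == "mesh":
        verts, faces, _ = _surface_mesh(mask.data)
        return float(mesh_surface_area(verts, faces)) * vs**2
    if method == "voxel_faces":
        d = mask.data
        faces = 0
        for axis in range(3):
            pad = np.zeros_like(d)
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[axis] = slice(None, -1)
            sl_hi[axis] = slice(1, None)
            diff = d[tuple(sl_lo)] != d[tuple(sl_hi)]
            faces += int(diff.sum())
            faces += int(d.take(0, axis=axis).sum() + d.take(-1, axis=axis).sum())
        return faces * vs**2
    raise ValueError(f"unknown surface method {method!r}")


def box_counts(mask: np.ndarray, box_sizes: list[int]) -> np.ndarray:
    """Occupied-box counts of a grid-aligned partition, one per box size."""
    counts = []
    for s in box_sizes:
        s = int(s)
        if s < 1:
            raise ValueError(f"box size must be >= 1, got {s}")
        padded_shape = [int(np.ceil(dim / s)) * s for dim in mask.shape]
        padded = np.zeros(padded_shape, dtype=bool)
        padded[: mask.shape[0], : mask.shape[1], : mask.shape[2]] = mask
        blocks = padded.reshape(
            padded_shape[0] // s, s, padded_shape[1] // s, s, padded_shape[2] // s, s
        )
        occupied = blocks.any(axis=(1, 3, 5))
        counts.append(int(occupied.sum()))
    return np.array(counts)


def default_box_sizes(shape: tuple[int, int, int]) -> list[int]:
    """Powers of two from 2 up to min(shape)/4."""
    top = min(shape) // 4
    sizes = []
    s = 2
    while s <= top:
        sizes.append(s)
        s *= 2
    return sizes


def fractal_dimension(mask: BinaryMask, box_sizes: list[int] | None = None) -> float:
    """Volume-occupancy box-counting dimension.

    FD is the negative slope of an unweighted least-squares fit of
    log(count) against log(size).  Requires >= 4 sizes spanning >= 2 octaves.
    """
    if not mask.data.any():
        raise ValueError("empty mask has no fractal dimension")
    sizes = default_box_sizes(mask.shape) if box_sizes is None else list(box_sizes)
    if len(sizes) < 4:
        raise ValueError(f"need >= 4 box sizes, got {len(sizes)}")
    if max(sizes) < 4 * min(sizes):
        raise ValueError(f"box sizes {sizes} must span at least 2 octaves")
    # anchor the partition at the foreground bounding box so the estimate does
    # not depend on where the structure sits inside the scan
    idx = np.nonzero(mask.data)
    lo = [int(i.min()) for i in idx]
    hi = [int(i.max()) + 1 for i in idx]
    cropped = mask.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    counts = box_counts(cropped, sizes)
    slope = np.polyfit(np.log(np.asarray(sizes, float)), np.log(counts.astype(float)), 1)[0]
    return float(-slope)


def structure_model_index(mask: BinaryMask, dilation_step: float | None = None) -> float:
    """SMI = 6 V S' / S**2, the differential-surface rod/plate index.

    S' is the derivative of surface area under an outward normal offset of the
    iso-surface: mesh vertices are displaced by ``dilation_step`` (mm, default
    half a voxel) along their normals and S' taken as the central difference.
    The mask must keep a background margin exceeding the dilation step.
    """
    vs = mask.voxel_size
    dr_mm = 0.5 * vs if dilation_step is None else float(dilation_step)
    dr_vox = dr_mm / vs
    if not mask.data.any():
        raise ValueError("empty mask has no SMI")
    if not mask.has_margin(max(2, int(np.ceil(dr_vox)) + 1)):
        raise ValueError(
            "mask touches the volume boundary: the offset surface is undefined "
            "without a background margin exceeding the dilation step"
        )
    sd = _signed_distance(mask.data)
    verts, faces, normals = _surface_mesh(mask.data)
    # orient normals outward: the signed field is positive inside, so moving
    # outward must lower the sampled field value
    probe = ndimage.map_coordinates(sd, (verts + 0.5 * normals).T, order=1)
    if float(np.median(probe)) > 0:
        normals = -normals
    s0 = float(mesh_surface_area(verts, faces))
    s_plus = float(mesh_surface_area(verts + dr_vox * normals, faces))
    s_minus = float(mesh_surface_area(verts - dr_vox * normals, faces))
    s_prime = (s_plus - s_minus) / (2.0 * dr_vox)
    v = float(mask.data.sum())
    return 6.0 * v * s_prime / s0**2


def vertical_length(
    mask: BinaryMask, reference_plane: int, direction: str = "+z"
) -> tuple[float, bool]:
    """Distance (mm) from the reference plane to the farthest plane with bone
    on the metaphysis side.

    Returns ``(length_mm, found_bone)``; when no bone lies past the reference
    the length is 0.0 and ``found_bone`` is False (a warning condition, not an
    error).
    """
    nz = mask.shape[0]
    ref = int(reference_plane)
    if not (0 <= ref < nz):
        raise ValueError(f"reference plane {ref} outside volume of {nz} planes")
    has_bone = mask.data.any(axis=(1, 2))
    if direction == "+z":
        planes = np.nonzero(has_bone[ref:])[0]
    elif direction == "-z":
        planes = np.nonzero(has_bone[: ref + 1][::-1])[0]
    else:
        raise ValueError(f"direction must be '+z' or '-z', got {direction!r}")
    if planes.size == 0:
        return 0.0, False
    return float(planes.max()) * mask.voxel_size, True


def compute_global_morphometry(
    mask: BinaryMask,
    tv_region: BinaryMask,
    reference_plane: int = 0,
    box_sizes: list[int] | None = None,
    dilation_step: float | None = None,
) -> GlobalMorphometry:
    """All global parameters of one specimen in a single call."""
    tv, bv, pct = compute_volumes(mask, tv_region)
    area = compute_surface_area(mask, method="mesh")
    fd = fractal_dimension(mask, box_sizes)
    smi = structure_model_index(mask, dilation_step)
    vlen, _ = vertical_length(mask, reference_plane)
    return GlobalMorphometry(
        total_tissue_volume=tv,
        bone_volume=bv,
        percent_bone_volume=pct,
        surface_area=area,
        sa_to_v=area / bv if bv > 0 else float("nan"),
        fractal_dimension=fd,
        smi=smi,
        vertical_length=vlen,
    )
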