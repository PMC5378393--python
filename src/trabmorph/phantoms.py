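"""Ground-truthed synthetic inputs: rod-network trabecular ROIs, the 5-insert
hydroxyapatite calibration phantom, analytic test solids, and two-group studies.

The trabecular generator emulates the cylindrical-rod view of cancellous bone:
a set of junction nodes connected by straight rods, each rod a capsule
(cylinder with hemispherical caps) of known length and radius.  Every output
carries its exact generative graph so downstream extraction can be scored
against truth.  The two-group generator programs the low-magnesium phenotype:
fewer rods and junctions and lower mineral intensity, with the per-rod length
and radius distributions left unchanged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .volume import BinaryMask, VoxelVolume

__all__ = [
    "DistSpec",
    "RodNetworkSpec",
    "GroundTruthGraph",
    "StudyEffectSpec",
    "StudyBundle",
    "StudySpecimen",
    "generate_rod_network",
    "generate_calibration_phantom",
    "generate_test_solid",
    "generate_two_group_study",
]


@dataclass(frozen=True)
class DistSpec:
    """A 1D sampling distribution for rod lengths or radii (values in mm)."""

    family: str  # "normal" | "lognormal" | "fixed"
    mean: float
    sd: float = 0.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "fixed" or self.sd == 0:
            return np.full(size, self.mean)
        if self.family == "normal":
            return rng.normal(self.mean, self.sd, size)
        if self.family == "lognormal":
            # parametrize by the arithmetic mean/sd of the lognormal itself
            var = self.sd**2
            mu = np.log(self.mean**2 / np.sqrt(var + self.mean**2))
            sigma = np.sqrt(np.log(1 + var / self.mean**2))
            return rng.lognormal(mu, sigma, size)
        raise ValueError(f"unknown distribution family {self.family!r}")

    def scaled(self, factor: float) -> "DistSpec":
        return DistSpec(self.family, self.mean * factor, self.sd * factor)


@dataclass
class RodNetworkSpec:
    """Generative parameters for one trabecular rod-network ROI.

    ``n_nodes`` counts the junction nodes placed in the box; free rod ends
    (endpoints) are added on top so every junction reaches degree >= 3.
    ``mean_degree`` sets the segment budget ``round(n_nodes * mean_degree / 2)``
    (junction-junction rods plus pendant rods), so the rod count scales
    linearly with the junction count.
    """

    volume_shape: tuple[int, int, int] = (120, 120, 120)
    voxel_size: float = 0.009
    n_nodes: int = 20
    mean_degree: float = 4.5
    length_dist: DistSpec = field(default_factory=lambda: DistSpec("normal", 0.27, 0.055))
    radius_dist: DistSpec = field(default_factory=lambda: DistSpec("normal", 0.032, 0.0045))
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.voxel_size > 0):
            raise ValueError("voxel_size must be > 0")
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if self.mean_degree < 1:
            raise ValueError("mean_degree must be >= 1")
        for name, dist in (("length_dist", self.length_dist), ("radius_dist", self.radius_dist)):
            if dist.mean <= 2 * self.voxel_size:
                raise ValueError(
                    f"{name} mean {dist.mean} mm is not resolvable at "
                    f"voxel size {self.voxel_size} mm (must exceed 2 voxels)"
                )


@dataclass
class GroundTruthGraph:
    """Exact generative truth: node positions (mm) and straight-rod segments."""

    node_positions: np.ndarray  # (n, 3) mm, order (z, y, x)
    node_kinds: list[str]  # "junction" | "endpoint"
    segments: list[tuple[int, int, float, float]]  # (node_a, node_b, length mm, radius mm)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_junctions(self) -> int:
        """Connecting nodes: junction-kind nodes of degree >= 3 (the same
        definition the measured graph uses)."""
        deg = self.degrees()
        return sum(1 for k, kind in enumerate(self.node_kinds) if kind == "junction" and deg[k] >= 3)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.node_kinds), dtype=int)
        for a, b, _, _ in self.segments:
            deg[a] += 1
            deg[b] += 1
        return deg

    def lengths(self) -> np.ndarray:
        return np.array([s[2] for s in self.segments])

    def radii(self) -> np.ndarray:
        return np.array([s[3] for s in self.segments])

    def validate(self) -> None:
        n = len(self.node_kinds)
        for a, b, length, radius in self.segments:
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"segment endpoint {a},{b} not a listed node")
            if radius <= 0:
                raise ValueError("segment radius must be > 0")
            d = float(np.linalg.norm(self.node_positions[a] - self.node_positions[b]))
            if abs(d - length) > 1e-9 + 1e-6 * max(d, length):
                raise ValueError(f"straight-rod length {length} != node distance {d}")


@dataclass
class StudyEffectSpec:
    """Programmed low-Mg vs basal contrast for a two-group synthetic study.

    ``segment_count_ratio`` and ``density_ratio`` scale the low-Mg group's rod
    budget and mineral intensity (both in (0, 1]); ``length_radius_shift``
    scales its length/radius distribution means (0 = unchanged, the headline
    morphological finding being emulated).
    """

    n_per_group: int = 8
    segment_count_ratio: float = 0.7
    density_ratio: float = 0.85
    length_radius_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("segment_count_ratio", "density_ratio"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2 (group statistics undefined below)")


# ---------------------------------------------------------------------------
# rasterization


def _rasterize_capsules(
    shape: tuple[int, int, int],
    endpoints_a: np.ndarray,
    endpoints_b: np.ndarray,
    radii_vox: np.ndarray,
) -> np.ndarray:
    """Union of capsules; a voxel is foreground iff its center lies inside one.

    Endpoints and radii are in voxel coordinates.  Hemispherical caps keep
    overlapping rods connected at shared junctions; overlaps are unioned.
    """
    mask = np.zeros(shape, dtype=bool)
    for a, b, r in zip(endpoints_a, endpoints_b, radii_vox):
        lo = np.floor(np.minimum(a, b) - r - 1).astype(int)
        hi = np.ceil(np.maximum(a, b) + r + 2).astype(int)
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, shape)
        if (hi <= lo).any():
            continue
        grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
        p = np.stack(grids, axis=-1).astype(float)
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            d2 = ((p - a) ** 2).sum(-1)
        else:
            t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
            proj = a + t[..., None] * ab
            d2 = ((p - proj) ** 2).sum(-1)
        sub = d2 <= r * r
        mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= sub
    return mask


# ---------------------------------------------------------------------------
# rod networks


def _seg_seg_dist(p1: np.ndarray, q1: np.ndarray, p2: np.ndarray, q2: np.ndarray) -> float:
    """Minimum distance between segments [p1,q1] and [p2,q2]."""
    d1, d2 = q1 - p1, q2 - p2
    r = p1 - p2
    a, e, f = d1 @ d1, d2 @ d2, d2 @ r
    if a <= 1e-12 and e <= 1e-12:
        return float(np.linalg.norm(r))
    if a <= 1e-12:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = d1 @ r
        if e <= 1e-12:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = d1 @ d2
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
            t = (b * s + f) / e
            if t < 0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    return float(np.linalg.norm(p1 + s * d1 - (p2 + t * d2)))


def _seg_point_dist(p: np.ndarray, q: np.ndarray, x: np.ndarray) -> float:
    d = q - p
    denom = float(d @ d)
    t = 0.0 if denom == 0 else float(np.clip(((x - p) @ d) / denom, 0.0, 1.0))
    return float(np.linalg.norm(p + t * d - x))


def _seg_to_segs_dist(
    p: np.ndarray, q: np.ndarray, A: np.ndarray, B: np.ndarray
) -> np.ndarray:
    """Distances from segment [p, q] to each segment [A[k], B[k]] (vectorized
    Ericson closest-point-of-segments with clamping)."""
    d1 = q - p  # (3,)
    d2 = B - A  # (n, 3)
    r = p - A  # (n, 3)
    a = float(d1 @ d1)
    e = (d2 * d2).sum(axis=1)
    f = (d2 * r).sum(axis=1)
    c = r @ d1
    b = d2 @ d1
    denom = a * e - b * b
    s = np.where(denom > 1e-12, (b * f - c * e) / np.where(denom > 1e-12, denom, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    t = np.where(e > 1e-12, (b * s + f) / np.where(e > 1e-12, e, 1.0), 0.0)
    # re-clamp s where t left [0, 1]
    t_cl = np.clip(t, 0.0, 1.0)
    need = t != t_cl
    if a > 1e-12 and need.any():
        s = np.where(need, np.clip((t_cl * b - c) / a, 0.0, 1.0), s)
    t = t_cl
    closest1 = p[None, :] + s[:, None] * d1[None, :]
    closest2 = A + t[:, None] * d2
    return np.linalg.norm(closest1 - closest2, axis=1)


_MIN_ROD_ANGLE_COS = np.cos(np.deg2rad(55.0))  # rods at a joint separate by >= 55 deg


def _build_truth_graph(spec: RodNetworkSpec, rng: np.random.Generator) -> GroundTruthGraph:
    vs = spec.voxel_size
    shape_mm = np.array(spec.volume_shape) * vs
    margin = max(
        3 * (spec.radius_dist.mean + 2 * abs(spec.radius_dist.sd)),
        3 * vs,
    )
    box_lo = np.full(3, margin)
    box_hi = shape_mm - margin
    if (box_hi <= box_lo).any():
        raise ValueError(
            f"volume {spec.volume_shape} too small for rods of radius "
            f"~{spec.radius_dist.mean} mm: no interior box remains"
        )
    L_mean = spec.length_dist.mean
    min_sep = max(0.45 * L_mean, 4 * vs)
    center = 0.5 * (box_lo + box_hi)
    first = center + rng.uniform(-0.1, 0.1, size=3) * (box_hi - box_lo)
    node_positions: list[np.ndarray] = [first]
    kinds = ["junction"]
    edges: list[tuple[int, int]] = []
    radii: list[float] = []
    node_ball: list[float] = [0.0]  # max incident rod radius per node
    adjacency: list[set[int]] = [set()]
    clearance = 2.0 * vs

    def register_edge(a: int, b: int, r: float) -> None:
        edges.append((a, b))
        radii.append(r)
        node_ball[a] = max(node_ball[a], r)
        node_ball[b] = max(node_ball[b], r)
        adjacency[a].add(b)
        adjacency[b].add(a)

    def draw_radius() -> float:
        return float(np.clip(spec.radius_dist.sample(rng, 1)[0], 1.2 * vs, None))

    def feasible(a: int, b_pos: np.ndarray, b_idx: int | None, r: float) -> bool:
        """Can a rod of radius r run from node a to b (index or new tip) without
        colliding with existing rods or foreign joints?

        Rods sharing a node must separate by a minimum angle; disjoint rods
        must keep a surface clearance, as must foreign junction balls.  The
        constraints make the drawn graph geometrically realizable, so the
        rasterized capsules only merge where the truth says they connect.
        """
        pa = node_positions[a]
        u = b_pos - pa
        un = np.linalg.norm(u)
        if un == 0:
            return False
        own = {a} if b_idx is None else {a, b_idx}
        if edges:
            E = np.array(edges)
            P = np.array(node_positions)
            shared_mask = np.isin(E[:, 0], list(own)) | np.isin(E[:, 1], list(own))
            # angle screen at shared joints
            for k in np.nonzero(shared_mask)[0]:
                i, j = edges[k]
                for sn in {i, j} & own:
                    pe = node_positions[i] if sn == j else node_positions[j]
                    v = pe - node_positions[sn]
                    vn = np.linalg.norm(v)
                    if vn == 0:
                        return False
                    w = (b_pos - node_positions[sn]) if sn == a else (pa - node_positions[sn])
                    wn = np.linalg.norm(w)
                    if wn == 0:
                        return False
                    if (v / vn) @ (w / wn) > _MIN_ROD_ANGLE_COS:
                        return False
            # clearance to all disjoint rods at once
            disjoint = np.nonzero(~shared_mask)[0]
            if disjoint.size:
                dists = _seg_to_segs_dist(pa, b_pos, P[E[disjoint, 0]], P[E[disjoint, 1]])
                if (dists < r + np.asarray(radii)[disjoint] + clearance).any():
                    return False
        # foreign joint balls must keep clear of the new rod; nodes adjacent
        # to the anchor are exempt (the angle screen governs those)
        P_all = np.array(node_positions)
        exempt = set(own) | adjacency[a]
        other = np.array([k not in exempt for k in range(len(node_positions))])
        if other.any():
            X = P_all[other]
            balls = np.array([node_ball[k] for k in range(len(node_positions))])[other]
            d = X - pa
            t = np.clip((d @ (b_pos - pa)) / (un**2), 0.0, 1.0)
            closest = pa[None, :] + t[:, None] * (b_pos - pa)[None, :]
            if (np.linalg.norm(X - closest, axis=1) < r + balls + clearance).any():
                return False
        return True

    # grow the junction tree: each new junction sits at an exactly-drawn rod
    # length from a random existing junction, so junction-junction rod lengths
    # follow length_dist regardless of how many junctions the box holds (the
    # two study groups differ only in their budgets, never in rod geometry)
    max_deg = int(np.ceil(spec.mean_degree)) + 2

    def degree(j: int) -> int:
        return sum(1 for a, b in edges if j in (a, b))

    growth_failures = 0
    while len(kinds) < spec.n_nodes and growth_failures < 20 * spec.n_nodes:
        L = max(float(spec.length_dist.sample(rng, 1)[0]), 2.5 * vs)
        if L < min_sep:
            # junction spacing below the separation floor is unresolvable;
            # the rejection depends only on the drawn length, never on
            # crowding, so both study groups see the same truncation
            continue
        r = draw_radius()
        placed = False
        for _ in range(80):
            u = int(rng.integers(len(kinds)))
            if degree(u) >= max_deg:
                continue
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            tip = node_positions[u] + L * direction
            if not ((tip >= box_lo).all() and (tip <= box_hi).all()):
                continue
            sep_ok = all(
                np.linalg.norm(tip - node_positions[k]) >= min_sep
                for k in range(len(kinds))
                if k != u
            )
            if not sep_ok or not feasible(u, tip, None, r):
                continue
            node_positions.append(tip)
            kinds.append("junction")
            node_ball.append(0.0)
            adjacency.append(set())
            register_edge(u, len(node_positions) - 1, r)
            placed = True
            break
        if not placed:
            growth_failures += 1
    n_junctions = len(kinds)

    # pendant rods: bring every junction to degree >= 3, then fill the segment
    # budget.  Each pendant keeps its drawn length while hunting for a
    # placement (junction and direction): resampling the length on failure
    # would couple the realized length distribution to crowding and so to the
    # group's rod budget — exactly the confound the study design excludes.
    def place_pendant(j: int, L: float, r: float, tries: int = 60) -> bool:
        for _ in range(tries):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            tip = node_positions[j] + L * direction
            if not ((tip >= box_lo).all() and (tip <= box_hi).all()):
                continue
            if not feasible(j, tip, None, r):
                continue
            node_positions.append(tip)
            kinds.append("endpoint")
            node_ball.append(0.0)
            adjacency.append(set())
            register_edge(j, len(node_positions) - 1, r)
            return True
        return False

    for j in range(n_junctions):
        retries = 0
        while degree(j) < 3 and retries < 8:
            L = max(float(spec.length_dist.sample(rng, 1)[0]), 2.5 * vs)
            if not place_pendant(j, L, draw_radius(), tries=90):
                retries += 1
    # fill the segment budget with pendant rods; the budget scales linearly
    # with the junction count, so group contrasts programmed through n_nodes
    # carry through to the segment count
    segment_budget = int(round(n_junctions * spec.mean_degree / 2.0))
    failures = 0
    while len(edges) < segment_budget and failures < 3 * n_junctions:
        L = max(float(spec.length_dist.sample(rng, 1)[0]), 2.5 * vs)
        r = draw_radius()
        placed = False
        for j in rng.permutation(n_junctions):
            if degree(int(j)) < max_deg and place_pendant(int(j), L, r, tries=30):
                placed = True
                break
        if not placed:
            failures += 1

    if not edges:
        raise ValueError("rod-network spec produced zero resolvable rods")

    # junctions that could not reach degree 3 in a crowded box are,
    # topologically, rod ends: record them as such
    for j in range(n_junctions):
        if degree(j) <= 1:
            kinds[j] = "endpoint"

    pos = np.array(node_positions)
    segments = []
    for (a, b), r in zip(edges, radii):
        length = float(np.linalg.norm(pos[a] - pos[b]))
        segments.append((a, b, length, float(r)))
    graph = GroundTruthGraph(node_positions=pos, node_kinds=kinds, segments=segments)
    graph.validate()
    return graph


def generate_rod_network(
    spec: RodNetworkSpec,
    foreground_intensity: float = 130.0,
    background_intensity: float = 25.0,
    noise_sd: float = 4.0,
) -> tuple[VoxelVolume, BinaryMask, GroundTruthGraph]:
    """Generate one trabecular ROI: grayscale volume, truth mask, truth graph.

    The grayscale volume assigns foreground a mineral-density-proportional
    intensity plus additive Gaussian noise; deterministic for a fixed
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    graph = _build_truth_graph(spec, rng)
    vs = spec.voxel_size
    # mm -> voxel coordinates (voxel centers at (i + 0.5) * vs)
    pos_vox = graph.node_positions / vs - 0.5
    a = np.array([pos_vox[s[0]] for s in graph.segments])
    b = np.array([pos_vox[s[1]] for s in graph.segments])
    r = np.array([s[3] for s in graph.segments]) / vs
    mask = _rasterize_capsules(tuple(spec.volume_shape), a, b, r)
    if not mask.any():
        raise ValueError("rod-network spec produced an empty mask")
    gray = np.where(mask, foreground_intensity, background_intensity).astype(np.float64)
    if noise_sd > 0:
        gray += rng.normal(0.0, noise_sd, size=gray.shape)
    return (
        VoxelVolume(data=gray, voxel_size=vs),
        BinaryMask(data=mask, voxel_size=vs),
        graph,
    )


# ---------------------------------------------------------------------------
# calibration phantom


def generate_calibration_phantom(
    voxel_size: float,
    insert_densities: list[float] = (200.0, 400.0, 600.0, 800.0, 1000.0),
    true_slope: float = 0.1,
    true_intercept: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int, int] = (32, 128, 128),
) -> tuple[VoxelVolume, list[BinaryMask]]:
    """Synthetic hydroxyapatite density phantom.

    A cylindrical epoxy body (nominally 32 mm in diameter, scaled to the
    requested voxel grid) carries one cylindrical insert per density, each
    nominally 5 mm in diameter and running the full length of the body, on a
    ring around the axis.  Insert grayscale is ``true_slope * density +
    true_intercept`` plus optional Gaussian noise; the epoxy base is given
    density 0 (grayscale = intercept).
    """
    densities = list(insert_densities)
    if len(densities) < 1:
        raise ValueError("at least one insert density required")
    if any(b <= a for a, b in zip(densities, densities[1:])):
        raise ValueError(f"insert densities must be strictly increasing, got {densities}")
    nz, ny, nx = shape
    body_r = 0.47 * min(ny, nx)  # voxels; nominal 32 mm diameter scaled to grid
    insert_r = body_r * (5.0 / 32.0)  # nominal 5 mm inserts, same scale
    ring_r = body_r * 0.62
    n = len(densities)
    if n > 1:
        chord = 2 * ring_r * np.sin(np.pi / n)
        if chord < 2.2 * insert_r:
            raise ValueError(
                f"{n} inserts of radius {insert_r:.1f} voxels do not fit on the "
                f"carrier ring (radius {ring_r:.1f} voxels) without overlap"
            )
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    body2d = (yy - cy) ** 2 + (xx - cx) ** 2 <= body_r**2
    gray2d = np.where(body2d, true_intercept, 0.0)
    insert_masks2d = []
    for k, dens in enumerate(densities):
        ang = 2 * np.pi * k / max(n, 1)
        iy, ix = cy + ring_r * np.sin(ang), cx + ring_r * np.cos(ang)
        m2d = (yy - iy) ** 2 + (xx - ix) ** 2 <= insert_r**2
        if not (m2d <= body2d).all():
            raise ValueError(f"insert {k} (density {dens}) does not fit inside the body")
        gray2d = np.where(m2d, true_slope * dens + true_intercept, gray2d)
        insert_masks2d.append(m2d)
    gray = np.broadcast_to(gray2d, shape).astype(np.float64).copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        gray += rng.normal(0.0, noise_sd, size=shape)
    volume = VoxelVolume(data=gray, voxel_size=voxel_size)
    masks = [
        BinaryMask(data=np.broadcast_to(m, shape).copy(), voxel_size=voxel_size)
        for m in insert_masks2d
    ]
    return volume, masks


# ---------------------------------------------------------------------------
# analytic test solids


def generate_test_solid(
    kind: str,
    size_voxels: int,
    thickness_or_radius: float = 0.0,
    voxel_size: float = 0.009,
    margin: int = 8,
) -> BinaryMask:
    """Ideal rasterized solids for analytic checks of SMI, FD and SA/V.

    ``kind``: ``cube`` (edge = size), ``plate`` (size x size x thickness),
    ``rod`` (axial length = size, radius = thickness_or_radius, axis z) or
    ``sphere`` (radius = thickness_or_radius).  A background margin of at
    least 2 voxels is enforced on all faces because the surface operators
    need background.
    """
    margin = int(margin)
    if margin < 2:
        raise ValueError("margin must be >= 2 voxels (surface operators need background)")
    size = int(size_voxels)
    t = float(thickness_or_radius)
    if kind == "cube":
        shape = (size + 2 * margin,) * 3
        mask = np.zeros(shape, dtype=bool)
        mask[margin : margin + size, margin : margin + size, margin : margin + size] = True
    elif kind == "plate":
        th = max(int(round(t)), 1)
        shape = (th + 2 * margin, size + 2 * margin, size + 2 * margin)
        mask = np.zeros(shape, dtype=bool)
        mask[margin : margin + th, margin : margin + size, margin : margin + size] = True
    elif kind == "sphere":
        r = t
        if r <= 0:
            raise ValueError("sphere requires thickness_or_radius > 0")
        n = int(np.ceil(2 * r)) + 2 * margin + 1
        shape = (n, n, n)
        c = (n - 1) / 2.0
        zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        mask = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r**2
    elif kind == "rod":
        r = t
        if r <= 0:
            raise ValueError("rod requires thickness_or_radius > 0")
        nside = int(np.ceil(2 * r)) + 2 * margin + 1
        shape = (size + 2 * margin, nside, nside)
        c = (nside - 1) / 2.0
        zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        mask = ((yy - c) ** 2 + (xx - c) ** 2 <= r**2) & (zz >= margin) & (zz < margin + size)
    else:
        raise ValueError(f"unknown solid kind {kind!r}")
    out = BinaryMask(data=mask, voxel_size=voxel_size)
    if not out.has_margin(2):
        raise ValueError(f"{kind} solid violates the 2-voxel background margin")
    return out


# ---------------------------------------------------------------------------
# two-group studies


@dataclass
class StudySpecimen:
    """One synthetic animal: its ROI volume/mask, generative truth and label."""

    specimen_id: str
    group: str
    spec: RodNetworkSpec
    truth: GroundTruthGraph
    volume: VoxelVolume | None = None
    mask: BinaryMask | None = None
    foreground_intensity: float = 130.0


@dataclass
class StudyBundle:
    specimens: list[StudySpecimen]
    base: RodNetworkSpec
    effect: StudyEffectSpec

    def group(self, label: str) -> list[StudySpecimen]:
        return [s for s in self.specimens if s.group == label]


def generate_two_group_study(
    base: RodNetworkSpec,
    effect: StudyEffectSpec,
    render_volumes: bool = True,
    animal_cv: float = 0.10,
    intensity_cv: float = 0.03,
    foreground_intensity: float = 130.0,
    background_intensity: float = 25.0,
    noise_sd: float = 4.0,
) -> StudyBundle:
    """Generate a basal vs low-Mg study of ``effect.n_per_group`` animals each.

    Low-Mg specimens draw their junction budget scaled by
    ``segment_count_ratio`` and their foreground intensity scaled by
    ``density_ratio``; the length/radius distributions are scaled by
    ``(1 - length_radius_shift)`` (identical across groups at shift 0).
    ``animal_cv`` adds between-animal variation to the junction budget and
    ``intensity_cv`` to mineral intensity.  Per-animal seeds derive
    deterministically from ``effect.seed``; ``render_volumes=False`` skips
    rasterization and returns truth graphs only (used for large replicate
    simulations on the generative truth).
    """
    ss = np.random.SeedSequence(effect.seed)
    specimens: list[StudySpecimen] = []
    n_total = 2 * effect.n_per_group
    children = ss.spawn(n_total)
    shift_factor = 1.0 - effect.length_radius_shift
    for idx in range(n_total):
        group = "basal" if idx < effect.n_per_group else "low_mg"
        count_ratio = 1.0 if group == "basal" else effect.segment_count_ratio
        dens_ratio = 1.0 if group == "basal" else effect.density_ratio
        child = children[idx]
        animal_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        animal_rng = np.random.default_rng(animal_seed)
        n_nodes = int(round(animal_rng.normal(base.n_nodes * count_ratio, animal_cv * base.n_nodes * count_ratio)))
        n_nodes = max(n_nodes, 4)
        length_dist = base.length_dist if group == "basal" else base.length_dist.scaled(shift_factor)
        radius_dist = base.radius_dist if group == "basal" else base.radius_dist.scaled(shift_factor)
        spec = RodNetworkSpec(
            volume_shape=base.volume_shape,
            voxel_size=base.voxel_size,
            n_nodes=n_nodes,
            mean_degree=base.mean_degree,
            length_dist=length_dist,
            radius_dist=radius_dist,
            seed=int(animal_rng.integers(2**31 - 1)),
        )
        fg = foreground_intensity * dens_ratio
        if intensity_cv > 0:
            fg *= 1.0 + animal_rng.normal(0.0, intensity_cv)
        if render_volumes:
            volume, mask, truth = generate_rod_network(
                spec,
                foreground_intensity=fg,
                background_intensity=background_intensity,
                noise_sd=noise_sd,
            )
        else:
            truth = _build_truth_graph(spec, np.random.default_rng(spec.seed))
            volume = mask = None
        k = idx if group == "basal" else idx - effect.n_per_group
        specimens.append(
            StudySpecimen(
                specimen_id=f"{group}_{k + 1:02d}",
                group=group,
                spec=spec,
                truth=truth,
                volume=volume,
                mask=mask,
                foreground_intensity=fg,
            )
        )
    return StudyBundle(specimens=specimens, base=base, effect=effect)
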