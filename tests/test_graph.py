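import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from trabmorph.graph import (
    GraphNode,
    GraphSegment,
    TrabecularGraph,
    build_graph,
    distance_map,
    distribution,
    find_local_maxima,
    prune_graph,
    segment_statistics,
    skeletonize,
)
from trabmorph.volume import BinaryMask

from conftest import VOXEL, capsule_mask


def extract(mask):
    skel = skeletonize(mask)
    df = distance_map(mask)
    g = build_graph(skel, df, tv=float(np.prod(mask.shape)) * mask.voxel_size**3, mask=mask)
    return prune_graph(g)


class TestDistanceMap:
    def test_single_voxel_reads_one_voxel_size(self):
        data = np.zeros((7, 7, 7), bool)
        data[3, 3, 3] = True
        df = distance_map(BinaryMask(data, 0.009))
        assert df[3, 3, 3] == pytest.approx(0.009)
        assert df[0, 0, 0] == 0.0

    def test_cylinder_axis_distance_is_the_radius_within_half_a_voxel(self):
        mask = capsule_mask((21, 21, 60), [10, 10, 10], [10, 10, 50], 6.0)
        df = distance_map(mask) / VOXEL
        axis = df[10, 10, 20:40]
        assert np.all(np.abs(axis - 6.0) <= 0.5 + 1e-9)

    def test_matches_the_quadratic_brute_force_search(self, rng):
        data = rng.random((12, 12, 12)) < 0.4
        data[0] = data[-1] = False
        mask = BinaryMask(data, 0.01)
        df = distance_map(mask)
        fg = np.argwhere(data)
        bg = np.argwhere(~data)
        brute = cdist(fg, bg).min(axis=1) * 0.01
        np.testing.assert_allclose(df[tuple(fg.T)], brute, rtol=1e-12)

    def test_all_foreground_volume_fails(self):
        with pytest.raises(ValueError, match="foreground"):
            distance_map(BinaryMask(np.ones((5, 5, 5), bool), 0.01))


class TestSkeletonize:
    def test_straight_rod_thins_to_a_path_near_the_axis(self):
        mask = capsule_mask((21, 21, 70), [10, 10, 10], [10, 10, 60], 5.0)
        skel = skeletonize(mask)
        pts = np.argwhere(skel.data)
        # every skeleton voxel within one voxel of the true axis
        assert np.abs(pts[:, :2] - 10).max() <= 1

    def test_component_count_is_preserved(self):
        m1 = capsule_mask((60, 30, 30), [10, 15, 15], [25, 15, 15], 4.0)
        m2 = capsule_mask((60, 30, 30), [40, 15, 15], [52, 15, 15], 4.0)
        mask = BinaryMask(m1.data | m2.data, VOXEL)
        skel = skeletonize(mask)
        from scipy import ndimage

        struct = np.ones((3, 3, 3), bool)
        assert ndimage.label(skel.data, structure=struct)[1] == 2

    def test_empty_mask_gives_empty_skeleton(self):
        skel = skeletonize(BinaryMask(np.zeros((6, 6, 6), bool), 0.01))
        assert skel.count() == 0

    def test_torus_skeleton_keeps_its_cycle(self):
        n = 64
        c = (n - 1) / 2
        zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        rho = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
        mask = BinaryMask((rho - 20) ** 2 + (zz - c) ** 2 <= 25, VOXEL)
        skel = skeletonize(mask)
        # topology oracle: cycle rank of the voxel adjacency graph
        pts = [tuple(p) for p in np.argwhere(skel.data)]
        G = nx.Graph()
        G.add_nodes_from(pts)
        ptset = set(pts)
        for p in pts:
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        q = (p[0] + dz, p[1] + dy, p[2] + dx)
                        if q != p and q in ptset:
                            G.add_edge(p, q)
        cycle_rank = G.number_of_edges() - G.number_of_nodes() + nx.number_connected_components(G)
        assert cycle_rank >= 1


class TestBuildGraph:
    def test_single_rod_recovery(self):
        mask = capsule_mask((30, 30, 80), [15, 15, 15], [15, 15, 65], 5.0)
        g = extract(mask)
        assert g.n_segments == 1
        kinds = sorted(n.kind for n in g.nodes)
        assert kinds == ["endpoint", "endpoint"]
        seg = g.segments[0]
        assert abs(seg.length / (50 * VOXEL) - 1) < 0.02
        assert abs(seg.radius / VOXEL - 5.0) <= 0.5

    def test_diagonal_rod_length_tracks_the_euclidean_distance(self):
        a, b = np.array([10.0, 10, 10]), np.array([50.0, 50, 50])
        mask = capsule_mask((64, 64, 64), a, b, 4.0)
        g = extract(mask)
        assert g.n_segments == 1
        true_len = np.linalg.norm(b - a) * VOXEL
        assert abs(g.segments[0].length / true_len - 1) < 0.02

    def test_y_junction_has_one_connecting_node_and_three_branches(self):
        c = np.array([40.0, 40, 40])
        ends = [c + [0, 0, 35.0], c + [0, 30, -18.0], c + [28, -20, -14.0]]
        from trabmorph.phantoms import _rasterize_capsules

        m = _rasterize_capsules(
            (80, 80, 80), np.array([c] * 3), np.array(ends), np.array([4.0, 4.0, 4.0])
        )
        g = extract(BinaryMask(m, VOXEL))
        assert g.n_segments == 3
        assert g.n_junctions == 1
        assert sum(1 for n in g.nodes if n.kind == "endpoint") == 3
        # Euler bookkeeping for a connected acyclic component
        assert g.n_segments == len(g.nodes) - 1

    def test_torus_graph_is_a_self_loop(self):
        n = 64
        c = (n - 1) / 2
        zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        rho = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
        mask = BinaryMask((rho - 20) ** 2 + (zz - c) ** 2 <= 25, VOXEL)
        g = extract(mask)
        assert g.n_segments == 1
        assert g.segments[0].node_a == g.segments[0].node_b

    def test_non_thin_input_is_rejected_with_coordinates(self):
        blob = BinaryMask(np.ones((6, 6, 6), bool), VOXEL)
        df = np.ones((6, 6, 6))
        with pytest.raises(ValueError, match="voxel"):
            build_graph(blob, df, tv=1.0)


def toy_graph(lengths, radii, ends, kinds, tv=1.0):
    nodes = [
        GraphNode(i, np.array([0.0, 0.0, float(i)]), k) for i, k in enumerate(kinds)
    ]
    segs = [
        GraphSegment(i, a, b, L, r)
        for i, ((a, b), L, r) in enumerate(zip(ends, lengths, radii))
    ]
    g = TrabecularGraph(nodes=nodes, segments=segs, tv=tv, voxel_size=0.009)
    g.recompute_degrees()
    return g


class TestPruneGraph:
    def test_zero_threshold_is_the_identity(self):
        g = toy_graph([0.1, 0.2], [0.01, 0.01], [(0, 1), (1, 2)], ["endpoint", "junction", "endpoint"])
        p = prune_graph(g, min_length=0.0, joint_scale=0.0)
        assert p.n_segments == 2

    def test_short_spur_is_removed_and_the_rod_merged(self):
        # a long rod broken by a junction carrying a 2-voxel spur
        kinds = ["endpoint", "junction", "endpoint", "endpoint"]
        g = toy_graph(
            [0.10, 0.12, 0.018],
            [0.01, 0.01, 0.01],
            [(0, 1), (1, 2), (1, 3)],
            kinds,
        )
        p = prune_graph(g, min_length=5 * 0.009)
        assert p.n_segments == 1
        assert p.segments[0].length == pytest.approx(0.22)
        # merged radius is length-weighted
        assert p.segments[0].radius == pytest.approx(0.01)

    def test_pruning_is_idempotent(self, small_network):
        _, (vol, mask, truth) = small_network
        skel = skeletonize(mask)
        df = distance_map(mask)
        g = build_graph(skel, df, tv=1.0, mask=mask)
        once = prune_graph(g)
        twice = prune_graph(once)
        assert twice.n_segments == once.n_segments
        assert len(twice.nodes) == len(once.nodes)
        np.testing.assert_allclose(sorted(twice.lengths()), sorted(once.lengths()))


class TestSegmentStatistics:
    def test_densities_are_counts_over_tv(self):
        g = toy_graph(
            [0.1] * 10,
            [0.01] * 10,
            [(i, i + 1) for i in range(10)],
            ["endpoint"] + ["junction"] * 10,
            tv=2.0,
        )
        s = segment_statistics(g)
        assert s.segment_count == 10
        assert s.segment_density == pytest.approx(5.0)
        assert s.segment_density * g.tv == pytest.approx(s.segment_count)

    def test_single_segment_statistics_are_its_own_values(self):
        g = toy_graph([0.25], [0.013], [(0, 1)], ["endpoint", "endpoint"])
        s = segment_statistics(g)
        assert s.mean_length == pytest.approx(0.25)
        assert s.mean_radius == pytest.approx(0.013)
        assert s.total_length == pytest.approx(0.25)
        assert s.node_count == 0  # no junction in a bare rod

    def test_empty_graph_warns_with_zeros(self):
        g = TrabecularGraph(nodes=[], segments=[], tv=1.0, voxel_size=0.009)
        s = segment_statistics(g)
        assert s.segment_count == 0 and s.warning is not None

    def test_zero_tv_fails(self):
        g = TrabecularGraph(nodes=[], segments=[], tv=0.0, voxel_size=0.009)
        with pytest.raises(ValueError, match="tv"):
            segment_statistics(g)


class TestDistribution:
    def test_hand_counted_histogram(self):
        d = distribution([1.0, 1.0, 2.0, 3.0], 1.0)
        np.testing.assert_array_equal(d.counts, [2, 1, 1])
        np.testing.assert_allclose(d.bin_edges, [1, 2, 3, 4])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        values=st.lists(st.floats(min_value=1e-4, max_value=1.0), min_size=1, max_size=60),
        bw=st.floats(min_value=1e-3, max_value=0.3),
    )
    def test_counts_always_sum_to_the_number_of_segments(self, values, bw):
        d = distribution(values, bw)
        assert d.counts.sum() == len(values)
        assert np.all(np.diff(d.bin_edges) > 0)

    def test_mixture_modes_fall_in_the_tallest_bins(self, rng):
        vals = np.concatenate([rng.normal(0.05, 0.006, 500), rng.normal(0.20, 0.015, 400)])
        d = distribution(vals, 0.0055)
        # the tallest bin of each component brackets its generative mode
        lower = d.bin_centers < 0.12
        peak_low = d.bin_centers[lower][np.argmax(d.counts[lower])]
        peak_high = d.bin_centers[~lower][np.argmax(d.counts[~lower])]
        assert abs(peak_low - 0.05) < 0.0055 * 1.5
        assert abs(peak_high - 0.20) < 0.0055 * 1.5

    def test_empty_values_fail(self):
        with pytest.raises(ValueError, match="empty"):
            distribution([], 0.1)


class TestLocalMaxima:
    def test_unimodal_histogram_has_exactly_one_peak(self, rng):
        from trabmorph.graph import SegmentDistribution

        counts = np.array([1, 3, 8, 15, 9, 4, 1])
        d = SegmentDistribution(bin_edges=np.arange(8.0), counts=counts)
        res = find_local_maxima(d, smoothing_window=1)
        assert res.positions == [3.5]
        assert res.global_maximum == 3.5

    def test_two_separated_modes_are_both_found(self, rng):
        vals = np.concatenate([rng.normal(0.010, 0.0015, 600), rng.normal(0.028, 0.002, 450)])
        d = distribution(vals, 0.00275)
        res = find_local_maxima(d)
        assert len(res.positions) == 2
        assert min(abs(np.array(res.positions) - 0.010)) <= 0.00275
        assert min(abs(np.array(res.positions) - 0.028)) <= 0.00275
        assert res.global_maximum == pytest.approx(res.positions[0])

    def test_flat_histogram_has_no_strict_maxima(self):
        from trabmorph.graph import SegmentDistribution

        d = SegmentDistribution(bin_edges=np.arange(7.0), counts=np.full(6, 5))
        assert find_local_maxima(d).positions == []

    def test_fewer_than_three_bins_fail(self):
        from trabmorph.graph import SegmentDistribution

        d = SegmentDistribution(bin_edges=np.arange(3.0), counts=np.array([1, 2]))
        with pytest.raises(ValueError, match="3 bins"):
            find_local_maxima(d)


class TestNetworkRecovery:
    def test_radius_recovery_on_isolated_oblique_rods(self):
        # |measured - true| <= 0.6 voxel across the 3-10 voxel radius range
        cases = [
            ((40, 40, 90), [20, 20, 12], [20, 20, 78], 3.0),
            ((50, 50, 90), [25, 20, 12], [20, 30, 75], 5.0),
            ((60, 60, 100), [30, 25, 14], [22, 38, 85], 7.0),
            ((70, 70, 110), [35, 30, 15], [28, 42, 95], 10.0),
        ]
        for shape, a, b, r in cases:
            g = extract(capsule_mask(shape, a, b, r))
            assert g.n_segments == 1
            assert abs(g.segments[0].radius / VOXEL - r) <= 0.6
            true_len = np.linalg.norm(np.array(b, float) - np.array(a, float)) * VOXEL
            assert abs(g.segments[0].length / true_len - 1) <= 0.02

    def test_histogram_conservation_on_a_generated_network(self, small_network):
        _, (vol, mask, truth) = small_network
        g = extract(mask)
        d = distribution(g.lengths(), 0.0055)
        assert d.counts.sum() == g.n_segments
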