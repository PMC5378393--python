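import numpy as np
import pytest

from trabmorph.phantoms import (
    DistSpec,
    RodNetworkSpec,
    StudyEffectSpec,
    generate_calibration_phantom,
    generate_rod_network,
    generate_test_solid,
    generate_two_group_study,
    _rasterize_capsules,
)
from trabmorph.stats import compare_groups

VOXEL = 0.009


class TestRasterization:
    def test_axis_aligned_cylinder_volume_matches_analytic_value(self):
        # capsule with length 50 between endpoints, radius 5, plus two
        # hemispherical caps
        m = _rasterize_capsules(
            (30, 30, 80), np.array([[15.0, 15, 15]]), np.array([[15.0, 15, 65]]), np.array([5.0])
        )
        analytic = np.pi * 25 * 50 + (4.0 / 3.0) * np.pi * 125
        assert abs(m.sum() / analytic - 1) < 0.05

    def test_disjoint_capsules_conserve_total_volume(self):
        A = np.array([[10.0, 10, 10], [10.0, 40, 10], [40.0, 25, 10]])
        B = np.array([[10.0, 10, 50], [10.0, 40, 50], [40.0, 25, 50]])
        R = np.array([3.0, 4.0, 5.0])
        m = _rasterize_capsules((60, 60, 70), A, B, R)
        analytic = sum(np.pi * r**2 * 40 + (4.0 / 3.0) * np.pi * r**3 for r in R)
        assert abs(m.sum() / analytic - 1) < 0.05


class TestRodNetwork:
    def test_truth_graph_is_internally_consistent(self, small_network):
        spec, (vol, mask, truth) = small_network
        truth.validate()
        deg = truth.degrees()
        for k, kind in enumerate(truth.node_kinds):
            if kind == "junction":
                assert deg[k] >= 2
            else:
                assert deg[k] == 1
        # nearly all requested junctions realize the degree >= 3 definition
        assert truth.n_junctions >= spec.n_nodes - 1

    def test_segment_budget_follows_mean_degree(self, small_network):
        spec, (_, _, truth) = small_network
        budget = round(spec.n_nodes * spec.mean_degree / 2)
        assert abs(truth.n_segments - budget) <= max(2, 0.1 * budget)

    def test_foreground_intensity_and_noise_are_applied(self, small_network):
        spec, (vol, mask, _) = small_network
        assert vol.data[mask.data].mean() > vol.data[~mask.data].mean() + 50

    def test_fixed_seed_reproduces_the_mask_bitwise(self):
        spec = RodNetworkSpec(volume_shape=(64, 64, 64), n_nodes=6, seed=77)
        _, m1, _ = generate_rod_network(spec)
        _, m2, _ = generate_rod_network(spec)
        np.testing.assert_array_equal(m1.data, m2.data)

    def test_unresolvable_rod_spec_is_rejected(self):
        with pytest.raises(ValueError, match="resolvable"):
            RodNetworkSpec(length_dist=DistSpec("fixed", 0.01), voxel_size=0.009)

    def test_volume_too_small_for_rods_fails(self):
        with pytest.raises(ValueError, match="too small"):
            generate_rod_network(RodNetworkSpec(volume_shape=(10, 10, 10), seed=0))


class TestCalibrationPhantom:
    def test_noise_free_insert_means_are_exactly_affine(self):
        densities = [200.0, 400.0, 600.0, 800.0, 1000.0]
        vol, masks = generate_calibration_phantom(
            0.035, densities, true_slope=0.1, true_intercept=10.0, noise_sd=0.0
        )
        assert len(masks) == 5
        for d, m in zip(densities, masks):
            assert vol.data[m.data].mean() == pytest.approx(0.1 * d + 10.0, abs=1e-9)

    def test_zero_density_insert_reads_the_intercept(self):
        vol, masks = generate_calibration_phantom(
            0.035, [0.0], true_slope=0.2, true_intercept=33.0, noise_sd=0.0
        )
        assert vol.data[masks[0].data].mean() == pytest.approx(33.0)

    def test_seeded_noise_is_reproducible(self):
        v1, _ = generate_calibration_phantom(0.035, [200.0, 400.0], noise_sd=3.0, seed=5)
        v2, _ = generate_calibration_phantom(0.035, [200.0, 400.0], noise_sd=3.0, seed=5)
        np.testing.assert_array_equal(v1.data, v2.data)

    def test_non_increasing_densities_are_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            generate_calibration_phantom(0.035, [400.0, 200.0])

    def test_overcrowded_insert_ring_fails(self):
        with pytest.raises(ValueError, match="fit"):
            generate_calibration_phantom(0.035, list(np.arange(100.0, 2100.0, 100.0)))


class TestTestSolids:
    def test_cube_has_exact_voxel_count(self):
        assert generate_test_solid("cube", 64).count() == 64**3

    def test_sphere_volume_matches_analytic_within_2_percent(self):
        mask = generate_test_solid("sphere", 0, 20.0)
        assert abs(mask.count() / ((4.0 / 3.0) * np.pi * 20.0**3) - 1) < 0.02

    def test_single_plane_plate_counts_4096(self):
        assert generate_test_solid("plate", 64, 1).count() == 4096

    def test_margin_floor_is_enforced(self):
        with pytest.raises(ValueError, match="margin"):
            generate_test_solid("cube", 16, margin=1)


class TestTwoGroupStudy:
    def test_programmed_effect_reaches_truth_counts_but_not_geometry(self):
        # count ratio 0.7 with zero shift: counts drop ~30%, rod geometry
        # stays put (n large enough that sampling noise sits well under the
        # 2% geometry bound)
        bundle = generate_two_group_study(
            RodNetworkSpec(seed=0), StudyEffectSpec(n_per_group=24, seed=0), render_volumes=False
        )
        basal = bundle.group("basal")
        low = bundle.group("low_mg")
        assert len(basal) == len(low) == 24
        count_drop = 1 - np.mean([s.truth.n_segments for s in low]) / np.mean(
            [s.truth.n_segments for s in basal]
        )
        assert 0.20 < count_drop < 0.40
        len_diff = abs(
            np.mean([s.truth.lengths().mean() for s in low])
            / np.mean([s.truth.lengths().mean() for s in basal])
            - 1
        )
        rad_diff = abs(
            np.mean([s.truth.radii().mean() for s in low])
            / np.mean([s.truth.radii().mean() for s in basal])
            - 1
        )
        assert len_diff < 0.02
        assert rad_diff < 0.02

    def test_zero_shift_means_identical_generative_distributions(self):
        bundle = generate_two_group_study(
            RodNetworkSpec(seed=0), StudyEffectSpec(seed=1), render_volumes=False
        )
        dists = {(s.spec.length_dist, s.spec.radius_dist) for s in bundle.specimens}
        assert len(dists) == 1

    def test_null_effect_rarely_flags_truth_counts(self):
        # exchangeable groups: the t-test on truth segment counts should stay
        # non-significant in the vast majority of replicate studies
        base = RodNetworkSpec(n_nodes=12, seed=0)
        rejections = 0
        n_rep = 50
        for rep in range(n_rep):
            effect = StudyEffectSpec(
                n_per_group=4, segment_count_ratio=1.0, density_ratio=1.0, seed=10_000 + rep
            )
            bundle = generate_two_group_study(base, effect, render_volumes=False)
            a = [s.truth.n_segments for s in bundle.group("basal")]
            b = [s.truth.n_segments for s in bundle.group("low_mg")]
            rejections += int(compare_groups(a, b).significant)
        assert rejections <= 0.10 * n_rep

    def test_fixed_study_seed_reproduces_the_bundle(self):
        base = RodNetworkSpec(volume_shape=(64, 64, 64), n_nodes=6, seed=0)
        effect = StudyEffectSpec(n_per_group=2, seed=9)
        b1 = generate_two_group_study(base, effect)
        b2 = generate_two_group_study(base, effect)
        for s1, s2 in zip(b1.specimens, b2.specimens):
            np.testing.assert_array_equal(s1.volume.data, s2.volume.data)
            np.testing.assert_array_equal(s1.mask.data, s2.mask.data)

    def test_single_animal_groups_are_rejected(self):
        with pytest.raises(ValueError, match="n_per_group"):
            StudyEffectSpec(n_per_group=1)
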