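import math

import numpy as np
import pytest

from vesselquant import (CohortSpec, PhantomSpec, amplitude_for_dm,
                         dm_for_amplitude, generate_cohort, generate_phantom,
                         make_arc_segment, rasterize)
from vesselquant.phantom import PftLink, sample_dm_targets
from tests.conftest import render, straight_tube_truth


class TestDistanceMetricMap:
    def test_zero_amplitude_is_straight(self):
        assert dm_for_amplitude(0.0) == 1.0
        assert amplitude_for_dm(1.0) == 0.0

    @pytest.mark.parametrize("dm", [1.005, 1.029, 1.1, 1.3])
    def test_inverse_map(self, dm):
        assert dm_for_amplitude(amplitude_for_dm(dm)) == pytest.approx(
            dm, abs=1e-9)

    def test_half_circle_arc_dm(self):
        # arc pi*r over chord 2r
        seg = make_arc_segment(15.0, math.pi)
        assert seg.distance_metric == pytest.approx(math.pi / 2, abs=1e-12)

    def test_quarter_circle_arc_dm(self):
        # arc (pi/2)r over chord r*sqrt(2)
        seg = make_arc_segment(20.0, math.pi / 2)
        assert seg.distance_metric == pytest.approx(
            (math.pi / 4) * math.sqrt(2), abs=1e-12)

    def test_dm_below_one_rejected(self):
        with pytest.raises(ValueError):
            amplitude_for_dm(0.99)


class TestTreeGeneration:
    def test_zero_amplitude_gives_dm_one(self):
        spec = PhantomSpec(seed=5, tortuosity_amplitude=0.0, n_trees=2,
                           segments_per_tree=(4, 4),
                           vessel_volume_fraction=None)
        truth = generate_phantom(spec)
        for s in truth.segments:
            assert s.distance_metric == pytest.approx(1.0, abs=1e-12)

    def test_all_dm_at_least_one(self, recovery_phantom):
        _, truth, _, _ = recovery_phantom
        assert all(s.distance_metric >= 1.0 for s in truth.segments)

    def test_arc_equals_chord_times_dm(self, recovery_phantom):
        _, truth, _, _ = recovery_phantom
        for s in truth.segments[:20]:
            assert s.arc_mm == pytest.approx(
                s.chord_mm * s.distance_metric, rel=1e-9)

    def test_centerlines_inside_lung(self, recovery_phantom):
        _, truth, _, masks = recovery_phantom
        lung = masks["lung"]
        for s in truth.segments:
            idx = np.rint(lung.world_to_index(s.points)).astype(int)
            assert lung.values[tuple(idx.T)].all()

    def test_deterministic_under_seed(self):
        spec = PhantomSpec(seed=11, n_trees=2, segments_per_tree=(5, 5),
                           vessel_volume_fraction=None)
        a = generate_phantom(spec)
        b = generate_phantom(spec)
        assert len(a.segments) == len(b.segments)
        np.testing.assert_array_equal(a.segments[0].points,
                                      b.segments[0].points)

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(radius_range=(50.0, 60.0), lung_axes=(40, 30, 20))

    def test_dm_target_sampling_moments(self):
        rng = np.random.default_rng(0)
        x = sample_dm_targets(rng, 200_000, 1.029, 0.058)
        assert np.median(x) == pytest.approx(1.029, abs=5e-4)
        assert (np.percentile(x, 85) - np.percentile(x, 15)
                ) == pytest.approx(0.058, abs=2e-3)


class TestRasterize:
    def test_parenchyma_level_without_vessels(self):
        from vesselquant.phantom import PhantomTruth
        truth = PhantomTruth(segments=[], airways=[], lung_axes=(20, 15, 12),
                             lung_centre=np.zeros(3), lung_volume_l=0.01)
        spec = PhantomSpec(lung_axes=(20, 15, 12), noise_sd=0.0,
                           partial_volume_sigma=0.0,
                           vessel_volume_fraction=None, seed=0)
        vol, masks = rasterize(truth, spec)
        inside = vol.values[masks["lung"].values > 0]
        assert inside.mean() == pytest.approx(-850.0, abs=1e-6)

    def test_tube_volume_matches_analytic(self, tube_scene):
        truth, vol, masks = tube_scene
        analytic = math.pi * 2.0 ** 2 * 60.0
        raster = masks["vessel"].volume_l() * 1e6
        assert raster == pytest.approx(analytic, rel=0.10)

    def test_raster_error_shrinks_with_spacing(self):
        truth = straight_tube_truth(radius=1.5)
        analytic = math.pi * 1.5 ** 2 * 60.0
        errs = []
        for sp in (1.0, 0.5):
            _, masks = render(truth, spacing=sp, noise=0.0)
            errs.append(abs(masks["vessel"].volume_l() * 1e6 - analytic))
        assert errs[1] < errs[0]

    def test_deterministic(self):
        spec = PhantomSpec(seed=3, n_trees=2, segments_per_tree=(4, 4),
                           lung_axes=(30, 25, 20))
        t = generate_phantom(spec)
        v1, _ = rasterize(t, spec)
        v2, _ = rasterize(t, spec)
        np.testing.assert_array_equal(v1.values, v2.values)

    def test_subvoxel_tube_rejected(self):
        truth = straight_tube_truth(radius=0.3)
        spec = PhantomSpec(lung_axes=truth.lung_axes, spacing=(0.7,) * 3,
                           vessel_volume_fraction=None, seed=0)
        with pytest.raises(ValueError, match="below one voxel"):
            rasterize(truth, spec)

    def test_artery_vein_masks_partition_vessel(self, recovery_phantom):
        _, _, _, masks = recovery_phantom
        av = (masks["artery"].values > 0) | (masks["vein"].values > 0)
        assert np.array_equal(av, masks["vessel"].values > 0)


class TestCohort:
    def test_zero_noise_gives_r2_one(self):
        import statsmodels.api as sm
        spec = CohortSpec(n_subjects=60, seed=4, pft_links={
            "tlc_pct_pred": PftLink({"normalized_vessel_volume_pct": -13.25},
                                    mean=67.2, noise_sd=0.0)})
        df = generate_cohort(spec)
        X = sm.add_constant(df["normalized_vessel_volume_pct"])
        fit = sm.OLS(df["tlc_pct_pred"], X).fit()
        assert fit.rsquared == pytest.approx(1.0, abs=1e-9)

    def test_large_sample_means_match_targets(self):
        df = generate_cohort(CohortSpec(n_subjects=10_000, seed=7))
        assert df.vessel_tortuosity.mean() == pytest.approx(1.029, abs=0.001)
        assert df.normalized_vessel_volume_pct.mean() == pytest.approx(
            3.6, abs=0.05)
        assert df.vessel_density_per_l.mean() == pytest.approx(361.5, rel=0.02)

    def test_physical_bounds_respected(self):
        df = generate_cohort(CohortSpec(n_subjects=3000, seed=8))
        assert (df.vessel_tortuosity >= 1.0).all()
        assert (df.total_lung_volume_l > 0).all()

    def test_volume_density_coupled(self):
        df = generate_cohort(CohortSpec(n_subjects=4000, seed=9))
        r = df.normalized_vessel_volume_pct.corr(df.vessel_density_per_l)
        assert r > 0.8

    def test_reproducible(self):
        a = generate_cohort(CohortSpec(n_subjects=50, seed=1))
        b = generate_cohort(CohortSpec(n_subjects=50, seed=1))
        assert a.equals(b)

    def test_rejects_tiny_cohort(self):
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=1)

    def test_rejects_unattainable_r2(self):
        with pytest.raises(ValueError):
            PftLink({"x": 1.0}, mean=0.0, target_r2=1.5)
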