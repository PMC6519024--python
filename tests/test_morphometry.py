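import math

import numpy as np
import pytest

from vesselquant import CtVolume, mean_lung_attenuation
from vesselquant.image_io import LabelMask
from vesselquant.morphometry import (assign_zones, normalized_volume,
                                     tortuosity_and_heterogeneity,
                                     vessel_density, zonal_split)
from vesselquant.vessel_extract import VesselSegment


def _seg(dm=1.0, vol_ml=1.0, mid_z=0.0):
    """A synthetic segment with prescribed DM, volume and midpoint z."""
    chord = 10.0
    pts = np.stack([np.linspace(0, chord, 11), np.zeros(11),
                    np.full(11, mid_z)], axis=1)
    # stretch interior points to realise the requested arc (zig in y)
    s = VesselSegment.from_geometry(pts, np.full(11, 1.0))
    s.distance_metric = dm
    s.arc_mm = chord * dm
    s.volume_ml = vol_ml
    return s


class TestScalars:
    def test_normalized_volume_arithmetic(self):
        # 140.4 mL of vessels in a 3.9 L lung is 3.6%
        segs = [_seg(vol_ml=140.4)]
        assert normalized_volume(segs, 3.9) == pytest.approx(3.6, abs=1e-12)

    def test_normalized_volume_empty(self):
        assert normalized_volume([], 3.9) == 0.0

    def test_normalized_volume_zero_region(self):
        with pytest.raises(ValueError):
            normalized_volume([], 0.0)

    def test_density_arithmetic(self):
        assert vessel_density([_seg()] * 100, 0.5) == pytest.approx(200.0)

    def test_density_cohort_scale(self):
        # 1410 segments in a 3.9 L lung gives the cohort-mean density
        assert vessel_density([_seg()] * 1410, 3.9) == pytest.approx(
            361.5, abs=0.1)

    def test_density_empty(self):
        assert vessel_density([], 1.0) == 0.0


class TestTortuosity:
    def test_degenerate_distribution(self):
        segs = [_seg(dm=1.029) for _ in range(7)]
        med, het = tortuosity_and_heterogeneity(segs)
        assert med == pytest.approx(1.029)
        assert het == pytest.approx(0.0)

    def test_two_point_interpolated_percentiles(self):
        # brute force on {1.0, 1.2}: P15 = 1.03, P85 = 1.17
        med, het = tortuosity_and_heterogeneity([_seg(1.0), _seg(1.2)])
        assert med == pytest.approx(1.1)
        assert het == pytest.approx(0.14)

    def test_uniform_limit(self):
        rng = np.random.default_rng(0)
        segs = [_seg(dm) for dm in rng.uniform(1.0, 1.1, 40_000)]
        _, het = tortuosity_and_heterogeneity(segs)
        assert het == pytest.approx(0.07, abs=0.002)

    def test_empty_is_nan_not_zero(self):
        med, het = tortuosity_and_heterogeneity([])
        assert math.isnan(med) and math.isnan(het)

    def test_single_segment_heterogeneity_undefined(self):
        med, het = tortuosity_and_heterogeneity([_seg(1.05)])
        assert med == pytest.approx(1.05)
        assert math.isnan(het)

    @pytest.mark.parametrize("trial", range(5))
    def test_percentiles_match_sort_interpolate_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        dms = 1.0 + rng.exponential(0.05, rng.integers(3, 1000))
        segs = [_seg(d) for d in dms]
        _, het = tortuosity_and_heterogeneity(segs)

        # independent oracle: sort, then linear interpolation between
        # order statistics at rank p*(n-1)
        x = np.sort(dms)
        n = len(x)

        def q(p):
            h = p * (n - 1)
            lo = int(math.floor(h))
            hi = min(lo + 1, n - 1)
            return x[lo] + (h - lo) * (x[hi] - x[lo])

        assert het == pytest.approx(q(0.85) - q(0.15), abs=1e-12)


class TestMeanLungAttenuation:
    def _scene(self):
        arr = np.full((20, 20, 20), -850.0, np.float32)
        lung = LabelMask(np.ones_like(arr, np.uint8), (1, 1, 1))
        return arr, lung

    def test_uniform_parenchyma(self):
        arr, lung = self._scene()
        assert mean_lung_attenuation(CtVolume(arr, (1, 1, 1)), lung) == \
            pytest.approx(-850.0)

    def test_vessels_excluded(self):
        arr, lung = self._scene()
        vmask = np.zeros_like(arr, np.uint8)
        vmask[5:8, 5:8, :] = 1
        arr[vmask > 0] = 50.0
        mla = mean_lung_attenuation(
            CtVolume(arr, (1, 1, 1)), lung,
            vessel=LabelMask(vmask, (1, 1, 1)))
        assert mla == pytest.approx(-850.0)

    def test_two_level_mean(self):
        arr, lung = self._scene()
        arr[:10] = -850.0
        arr[10:] = -750.0
        assert mean_lung_attenuation(CtVolume(arr, (1, 1, 1)), lung) == \
            pytest.approx(-800.0)

    def test_empty_residual_rejected(self):
        arr, lung = self._scene()
        with pytest.raises(ValueError):
            mean_lung_attenuation(CtVolume(arr, (1, 1, 1)), lung,
                                  vessel=lung)


class TestZones:
    def test_uniform_cylinder_equal_slabs(self):
        arr = np.zeros((10, 10, 30), np.uint8)
        arr[2:8, 2:8, :] = 1
        lung = LabelMask(arr, (1, 1, 1))
        masks, cuts = zonal_split(lung)
        counts = [int((masks[z].values > 0).sum()) for z in
                  ("lower", "middle", "upper")]
        assert counts == [36 * 10] * 3

    def test_cone_zones_equal_volume_not_equal_height(self):
        # radius grows with z: cuts must sit higher than z/3 and 2z/3
        nz = 60
        arr = np.zeros((50, 50, nz), np.uint8)
        for k in range(nz):
            r = 3 + 18 * k / (nz - 1)
            y, x = np.meshgrid(np.arange(50), np.arange(50), indexing="ij")
            arr[:, :, k] = ((x - 25) ** 2 + (y - 25) ** 2 <= r * r)
        lung = LabelMask(arr, (1, 1, 1))
        masks, cuts = zonal_split(lung)
        total = (arr > 0).sum()
        for z in ("lower", "middle", "upper"):
            frac = (masks[z].values > 0).sum() / total
            # within one axial slab of a third
            slab = (arr[:, :, -1] > 0).sum() / total
            assert abs(frac - 1 / 3) <= slab
        # oracle: cumulative-volume crossing, not geometric thirds
        cum = np.cumsum((arr > 0).sum(axis=(0, 1)))
        k1 = int(np.searchsorted(cum, total / 3))
        assert k1 > nz / 3

    def test_zone_conservation(self):
        arr = np.zeros((10, 10, 30), np.uint8)
        arr[2:8, 2:8, :] = 1
        lung = LabelMask(arr, (1, 1, 1))
        masks, cuts = zonal_split(lung)
        merged = sum((masks[z].values > 0).astype(int)
                     for z in ("lower", "middle", "upper"))
        assert (merged == (arr > 0).astype(int)).all()

    def test_midpoint_tie_goes_caudal(self):
        cuts = (10.0, 20.0)
        seg = _seg(mid_z=10.0)       # exactly on the lower/middle plane
        assign_zones([seg], cuts)
        assert seg.zone == "lower"

    def test_thin_lung_rejected(self):
        arr = np.zeros((10, 10, 4), np.uint8)
        arr[2:8, 2:8, 1:3] = 1
        with pytest.raises(ValueError, match="3 slices"):
            zonal_split(LabelMask(arr, (1, 1, 1)))
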