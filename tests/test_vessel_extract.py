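import math

import numpy as np
import pytest

from vesselquant import (CtVolume, build_trees, compute_vesselness,
                         detect_junctions, extract_paths, filter_by_diameter,
                         median_prefilter)
from vesselquant.image_io import LabelMask
from vesselquant.phantom import PhantomTruth, SegmentTruth
from vesselquant.vessel_extract import VesselSegment
from tests.conftest import render, straight_tube_truth


@pytest.fixture(scope="module")
def tube_field(tube_scene):
    truth, vol, masks = tube_scene
    return compute_vesselness(median_prefilter(vol), masks["lung"],
                              intensity=vol)


class TestVesselness:
    def test_on_axis_dominates_off_axis(self, tube_field):
        f = tube_field
        on = f.response[tuple(np.rint(f.world_to_index([0, 0, 0])).astype(int))]
        off = f.response[tuple(np.rint(
            f.world_to_index([0, 8.0, 0])).astype(int))]  # 2 diameters out
        assert on > 10 * max(off, 1e-6)

    def test_orientation_along_tube_axis(self, tube_field):
        f = tube_field
        o = f.orientation[tuple(np.rint(
            f.world_to_index([5, 0, 0])).astype(int))]
        assert abs(o[0]) > 0.99

    def test_uniform_volume_is_silent(self):
        vol = CtVolume(np.full((40, 40, 40), -850.0, np.float32),
                       spacing=(0.7,) * 3)
        lung = LabelMask(np.ones((40, 40, 40), np.uint8), vol.spacing,
                         vol.origin)
        f = compute_vesselness(vol, lung)
        assert float(f.response.max()) == pytest.approx(0.0, abs=1e-6)

    def test_too_few_scales_rejected(self, tube_scene):
        _, vol, masks = tube_scene
        with pytest.raises(ValueError, match="3 scales"):
            compute_vesselness(vol, masks["lung"], scales_mm=(1.0, 2.0))

    def test_unresolvable_scale_rejected(self, tube_scene):
        _, vol, masks = tube_scene
        with pytest.raises(ValueError, match="resolvable"):
            compute_vesselness(vol, masks["lung"],
                               scales_mm=(0.1, 1.0, 2.0))


class TestTracing:
    def test_single_tube_single_accurate_path(self, tube_field):
        paths = extract_paths(tube_field)
        assert len(paths) == 1
        pts = paths[0].points
        dev = np.sqrt(pts[:, 1] ** 2 + pts[:, 2] ** 2)
        assert np.sqrt((dev ** 2).mean()) < 0.5 * 0.5  # < half the voxel

    def test_tube_radius_estimate(self, tube_field):
        paths = extract_paths(tube_field)
        assert np.median(paths[0].radii) == pytest.approx(2.0, abs=0.5)

    def test_empty_field_empty_paths(self):
        shape = (20, 20, 20)
        from vesselquant.vessel_extract import VesselnessField
        f = VesselnessField(response=np.zeros(shape, np.float32),
                            radius_mm=np.zeros(shape, np.float32),
                            orientation=np.zeros(shape + (3,), np.float32),
                            spacing=np.array([1.0] * 3),
                            origin=np.zeros(3),
                            hu=np.full(shape, -850.0, np.float32))
        assert extract_paths(f) == []

    def test_two_parallel_tubes_stay_separate(self):
        segs = []
        for yc in (-6.0, 6.0):     # 3 radii apart at r = 2
            pts = np.stack([np.linspace(-25, 25, 101),
                            np.full(101, yc), np.zeros(101)], axis=1)
            segs.append(SegmentTruth(points=pts, radius_mm=2.0, tree_id=0,
                                     compartment="vein", arc_mm=50.0,
                                     chord_mm=50.0, distance_metric=1.0))
        truth = PhantomTruth(segments=segs, airways=[],
                             lung_axes=(35, 14, 10), lung_centre=np.zeros(3),
                             lung_volume_l=0.02)
        vol, masks = render(truth, spacing=0.7)
        f = compute_vesselness(median_prefilter(vol), masks["lung"],
                               intensity=vol)
        paths = extract_paths(f)
        # every path stays on one tube (no cross-links between tubes)
        for p in paths:
            assert (p.points[:, 1] > 0).all() or (p.points[:, 1] < 0).all()
        trees = build_trees(paths, vol.spacing,
                            junctions=detect_junctions(f), field=f)
        assert len(trees) == 2
        sides = [{np.sign(round(float(s.midpoint[1]), 3))
                  for s in t.segments} for t in trees]
        assert sides[0].isdisjoint(sides[1])


class TestTrees:
    def test_y_phantom_topology(self, y_scene):
        truth, vol, masks = y_scene
        f = compute_vesselness(median_prefilter(vol), masks["lung"],
                               intensity=vol)
        paths = extract_paths(f)
        trees = build_trees(paths, vol.spacing,
                            junctions=detect_junctions(f), field=f)
        assert len(trees) == 1
        assert len(trees[0].segments) == 3
        assert trees[0].n_bifurcations == 1

    def test_straight_tube_tree_and_volume(self, tube_field, tube_scene):
        truth, vol, _ = tube_scene
        paths = extract_paths(tube_field)
        trees = build_trees(paths, vol.spacing,
                            junctions=detect_junctions(tube_field),
                            field=tube_field)
        assert len(trees) == 1
        seg = trees[0].segments[0]
        assert seg.distance_metric == pytest.approx(1.0, abs=0.005)
        analytic_ml = math.pi * 4.0 * 60.0 / 1e3
        assert trees[0].total_volume_ml == pytest.approx(analytic_ml,
                                                         rel=0.15)

    def test_trees_are_acyclic(self, recovery_phantom):
        _, truth, vol, masks = recovery_phantom
        f = compute_vesselness(median_prefilter(vol), masks["lung"],
                               intensity=vol)
        paths = extract_paths(f)
        trees = build_trees(paths, vol.spacing,
                            junctions=detect_junctions(f), field=f)
        for t in trees:
            assert t.graph.number_of_edges() == t.graph.number_of_nodes() - 1


def _seg_with_diameter(d):
    pts = np.stack([np.linspace(0, 20, 21), np.zeros(21), np.zeros(21)],
                   axis=1)
    return VesselSegment.from_geometry(pts, np.full(21, d / 2.0))


class TestDiameterFilter:
    def test_band_examples(self):
        segs = {d: _seg_with_diameter(d) for d in (1.5, 5.0, 12.0)}
        kept = filter_by_diameter(list(segs.values()))
        assert kept == [segs[5.0]]

    def test_bounds_inclusive(self):
        segs = [_seg_with_diameter(d) for d in (1.99, 2.0, 10.0, 10.01)]
        kept = filter_by_diameter(segs)
        assert [round(s.mean_diameter_mm, 2) for s in kept] == [2.0, 10.0]

    def test_empty_input(self):
        assert filter_by_diameter([]) == []

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            filter_by_diameter([], min_mm=10, max_mm=2)


class TestSegmentGeometry:
    def test_dm_scale_invariance(self):
        rng = np.random.default_rng(5)
        pts = np.cumsum(rng.normal(0, 1, (30, 3)), axis=0)
        radii = rng.uniform(1, 2, 30)
        s1 = VesselSegment.from_geometry(pts, radii)
        s2 = VesselSegment.from_geometry(3.0 * pts, 3.0 * radii)
        assert s2.distance_metric == pytest.approx(s1.distance_metric,
                                                   rel=1e-12)
        assert s2.volume_ml == pytest.approx(27.0 * s1.volume_ml, rel=1e-12)

    def test_frustum_volume_of_cylinder(self):
        s = _seg_with_diameter(4.0)
        assert s.volume_ml == pytest.approx(math.pi * 4.0 * 20.0 / 1e3,
                                            rel=1e-9)

    def test_midpoint_of_straight_segment(self):
        s = _seg_with_diameter(4.0)
        np.testing.assert_allclose(s.midpoint, [10.0, 0.0, 0.0], atol=1e-9)
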