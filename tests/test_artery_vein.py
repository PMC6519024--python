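import numpy as np
import pytest

from vesselquant import (PhantomSpec, generate_phantom, quantify_volume,
                         rasterize)
from vesselquant.artery_vein import (airway_centerlines, av_excluded,
                                     av_misclassification, score_and_label,
                                     truth_labels_for_segments)
from vesselquant.image_io import LabelMask
from vesselquant.vessel_extract import VesselSegment, VesselTree
import networkx as nx


def _mask_from_tube(shape, axis_y, radius_vox):
    arr = np.zeros(shape, np.uint8)
    y, z = np.meshgrid(np.arange(shape[1]), np.arange(shape[2]),
                       indexing="ij")
    disc = (y - axis_y) ** 2 + (z - shape[2] // 2) ** 2 <= radius_vox ** 2
    arr[3:-3, disc] = 1
    return LabelMask(arr, spacing=(0.7, 0.7, 0.7))


class TestAirwayCenterlines:
    def test_straight_tube_single_path(self):
        mask = _mask_from_tube((60, 30, 30), 15, 2.5)
        paths = airway_centerlines(mask)
        assert len(paths) == 1
        pts, dirs = paths[0]
        assert abs(dirs[:, 0]).mean() > 0.95    # runs along x

    def test_empty_mask_warns(self):
        mask = LabelMask(np.zeros((10, 10, 10), np.uint8),
                         spacing=(1, 1, 1))
        with pytest.warns(UserWarning, match="empty airway"):
            assert airway_centerlines(mask) == []


def _toy_tree(tree_id, y_offset, r=1.5):
    pts = np.stack([np.linspace(-20, 20, 41), np.full(41, y_offset),
                    np.zeros(41)], axis=1)
    seg = VesselSegment.from_geometry(pts, np.full(41, r), tree_id=tree_id,
                                      segment_id=0)
    g = nx.Graph()
    g.add_edge(0, 1, segment=seg)
    g.nodes[0]["pos"] = pts[0]
    g.nodes[1]["pos"] = pts[-1]
    return VesselTree(tree_id=tree_id, graph=g, segments=[seg])


class TestScoreAndLabel:
    def test_airway_paired_artery_vs_distant_vein(self):
        artery = _toy_tree(0, y_offset=0.0)
        vein = _toy_tree(1, y_offset=20.0)
        # airway parallel to the artery at 1.5 radii offset
        apts = np.stack([np.linspace(-20, 20, 41),
                         np.full(41, 1.5 * 1.5), np.zeros(41)], axis=1)
        adirs = np.tile([1.0, 0, 0], (41, 1))
        scores = score_and_label([artery, vein], [(apts, adirs)])
        assert artery.segments[0].compartment == "artery"
        assert vein.segments[0].compartment == "vein"
        assert scores[0] > scores[1]

    def test_no_airway_leaves_unlabelled(self):
        tree = _toy_tree(0, 0.0)
        with pytest.warns(UserWarning):
            from vesselquant.artery_vein import airway_centerlines
            paths = airway_centerlines(
                LabelMask(np.zeros((5, 5, 5), np.uint8), spacing=(1, 1, 1)))
        score_and_label([tree], paths)
        assert tree.segments[0].compartment is None

    def test_labels_translation_invariant(self):
        t1 = _toy_tree(0, 0.0)
        apts = np.stack([np.linspace(-20, 20, 41), np.full(41, 2.25),
                         np.zeros(41)], axis=1)
        adirs = np.tile([1.0, 0, 0], (41, 1))
        score_and_label([t1], [(apts, adirs)])
        lab1 = t1.segments[0].compartment

        shift = np.array([100.0, -50.0, 30.0])
        t2 = _toy_tree(0, 0.0)
        t2.segments[0].points = t2.segments[0].points + shift
        score_and_label([t2], [(apts + shift, adirs)])
        assert t2.segments[0].compartment == lab1


class TestMisclassification:
    def test_perfect_labels(self):
        f = av_misclassification(["artery", "vein"], ["artery", "vein"],
                                 [1.0, 2.0])
        assert f == 0.0
        assert not av_excluded(f)

    def test_quarter_mislabelled_excluded(self):
        assert av_excluded(0.25)

    def test_exactly_twenty_percent_not_excluded(self):
        assert not av_excluded(0.20)

    def test_volume_weighting(self):
        f = av_misclassification(["artery", "artery"], ["artery", "vein"],
                                 [3.0, 1.0])
        assert f == pytest.approx(0.25)

    def test_total_swap_is_full_misclassification(self):
        f = av_misclassification(["vein", "artery"], ["artery", "vein"],
                                 [1.0, 1.0])
        assert f == 1.0

    def test_artery_vein_volumes_partition_labelled_total(self):
        segs = [VesselSegment.from_geometry(
            np.stack([np.linspace(0, 10, 11), np.zeros(11),
                      np.full(11, 3.0 * i)], axis=1), np.full(11, 1.0),
            compartment=("artery" if i % 2 else "vein")) for i in range(6)]
        va = sum(s.volume_ml for s in segs if s.compartment == "artery")
        vv = sum(s.volume_ml for s in segs if s.compartment == "vein")
        assert va + vv == pytest.approx(sum(s.volume_ml for s in segs))


def test_phantom_av_labels_mostly_correct(recovery_phantom):
    """On airway-paired phantoms the bronchus rule recovers most of the
    arterial volume."""
    spec, truth, vol, masks = recovery_phantom
    res = quantify_volume(vol, lung_mask=masks["lung"],
                          airway_mask=masks["airway"], truth=truth,
                          truth_masks=masks)
    f = res.qc_report.frac_av_mislabelled
    assert f is not None and f < 0.20
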