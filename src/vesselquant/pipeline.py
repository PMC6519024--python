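"""End-to-end orchestration: simulate -> quantify -> cohort.

A single :class:`RunConfig` carries every tunable threshold of the
pipeline; unknown YAML keys are rejected, and the effective config is
echoed into each output directory for provenance.  One global seed fans
out deterministically to per-stage seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import artery_vein, morphometry, preprocess, qc, vessel_extract
from .image_io import (CtVolume, LabelMask, read_mask, read_volume,
                       write_segments_csv, write_volume)
from .phantom import (PhantomSpec, PhantomTruth, SegmentTruth,
                      generate_phantom, make_arc_segment, rasterize)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every tunable of the quantitation pipeline, with defaults."""

    scales_mm: tuple = vessel_extract.DEFAULT_SCALES_MM
    seed_threshold: float = 0.05
    trace_threshold: float = 0.01
    min_diameter_mm: float = vessel_extract.MIN_DIAMETER_MM
    max_diameter_mm: float = vessel_extract.MAX_DIAMETER_MM
    boundary_erosion_mm: float = 2.0
    prefilter: bool = True
    av_enabled: bool = True
    artery_score_threshold: float = artery_vein.ARTERY_SCORE_THRESHOLD
    seed: int = 0
    verbosity: str = "info"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def echo(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "effective_config.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed below 2^31."""
        h = 0
        for ch in stage:
            h = (h * 131 + ord(ch)) % 1_000_003
        return (self.seed * 1_000_003 + h) % (2 ** 31)


@dataclass
class SubjectResult:
    metrics: morphometry.SubjectMetrics
    segments: list
    trees: list
    qc_report: object = None
    prep: object = None


def quantify_volume(vol: CtVolume, lung_mask: LabelMask | None = None,
                    airway_mask: LabelMask | None = None,
                    airway_seed=None, truth: PhantomTruth | None = None,
                    truth_masks: dict | None = None,
                    config: RunConfig | None = None) -> SubjectResult:
    """Run the full quantitation chain on one CT volume.

    External lung/airway masks are used when given; otherwise the
    built-in threshold/region-growing fallbacks run.  When phantom truth
    is supplied the QC fractions and artery/vein mislabelling are
    computed against it.
    """
    cfg = config or RunConfig()
    prep = preprocess.prepare(vol, lung_mask, airway_mask, airway_seed,
                              prefilter=cfg.prefilter)
    trees, segments = vessel_extract.extract_vessels(
        prep.filtered, prep.lung, cfg.scales_mm,
        min_diameter_mm=cfg.min_diameter_mm,
        max_diameter_mm=cfg.max_diameter_mm, intensity=vol,
        boundary_erosion_mm=cfg.boundary_erosion_mm,
        seed_threshold=cfg.seed_threshold,
        trace_threshold=cfg.trace_threshold)
    # prune trees to the filtered segment set for AV labelling
    kept = set(id(s) for s in segments)
    trees = [t for t in trees if any(id(s) in kept for s in t.segments)]
    for t in trees:
        t.segments = [s for s in t.segments if id(s) in kept]

    frac_av = None
    if cfg.av_enabled and prep.airway.values.any():
        airway_paths = artery_vein.airway_centerlines(prep.airway)
        artery_vein.score_and_label(
            trees, airway_paths, threshold=cfg.artery_score_threshold)
        if truth is not None:
            true_lab = artery_vein.truth_labels_for_segments(segments, truth)
            frac_av = artery_vein.av_misclassification(
                [s.compartment for s in segments], true_lab,
                [s.volume_ml for s in segments])
    else:
        for s in segments:
            s.compartment = None

    vessel_mask = vessel_extract.segments_to_mask(segments, vol)
    metrics = morphometry.compute_subject_metrics(
        vol, prep.lung, segments, airway=prep.airway,
        vessel_mask=vessel_mask,
        av_labelled=cfg.av_enabled)

    report = None
    if truth_masks is not None and "vessel" in truth_masks:
        report = qc.qc_against_truth(vessel_mask, truth_masks["vessel"],
                                     frac_av_mislabelled=frac_av)
    return SubjectResult(metrics=metrics, segments=segments, trees=trees,
                         qc_report=report, prep=prep)


def run_subject(config: RunConfig, ct_path, lung_mask_path=None,
                airway_mask_path=None, airway_seed=None,
                out_dir=None) -> SubjectResult:
    """File-level entry point: read inputs, quantify, write outputs."""
    ct_path = Path(ct_path)
    if not ct_path.exists():
        raise FileNotFoundError(ct_path)
    vol = read_volume(ct_path)
    lung = read_mask(lung_mask_path) if lung_mask_path else None
    airway = read_mask(airway_mask_path) if airway_mask_path else None
    result = quantify_volume(vol, lung, airway, airway_seed, config=config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        config.echo(out_dir)
        result.metrics.to_json(out_dir / "metrics.json")
        write_segments_csv(result.segments, out_dir / "segments.csv")
        _write_trees_json(result.trees, out_dir / "trees.json")
        if result.qc_report is not None:
            result.qc_report.to_json(out_dir / "qc.json")
    return result


def _write_trees_json(trees, path):
    data = []
    for t in trees:
        edges = []
        for u, v, d in t.graph.edges(data=True):
            seg = d.get("segment")
            edges.append({"u": str(u), "v": str(v),
                          "segment_id": seg.segment_id if seg else None})
        data.append({"tree_id": t.tree_id,
                     "n_segments": len(t.segments),
                     "n_bifurcations": t.n_bifurcations,
                     "edges": edges})
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)


def simulate_subject(spec: PhantomSpec, out_dir=None):
    """Generate a phantom, optionally writing volume/masks/truth to disk."""
    truth = generate_phantom(spec)
    vol, masks = rasterize(truth, spec)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_volume(vol, out_dir / "volume.nii.gz")
        for name, m in masks.items():
            write_volume(m, out_dir / f"{name}.nii.gz")
        truth.segment_frame().to_csv(out_dir / "truth.csv", index=False)
        with open(out_dir / "phantom.json", "w") as fh:
            json.dump({"lung_volume_l": masks["lung"].volume_l(),
                       "analytic_lung_volume_l": truth.lung_volume_l,
                       "n_segments": len(truth.segments)}, fh, indent=2)
    return truth, vol, masks


def run_phantom_subject(spec: PhantomSpec,
                        config: RunConfig | None = None) -> dict:
    """Phantom end-to-end: simulate, quantify against truth, summarise."""
    truth, vol, masks = simulate_subject(spec)
    result = quantify_volume(vol, lung_mask=masks["lung"],
                             airway_mask=masks["airway"],
                             truth=truth, truth_masks=masks, config=config)
    m = result.metrics
    tdf = truth.segment_frame()
    return {
        "truth": {
            "n_segments": len(truth.segments),
            "dm_median": float(tdf.distance_metric.median()),
            "dm_width": float(np.percentile(tdf.distance_metric, 85)
                              - np.percentile(tdf.distance_metric, 15)),
            "vessel_volume_ml": truth.total_vessel_volume_ml,
            "lung_volume_l": masks["lung"].volume_l(),
        },
        "measured": m.flat,
        "metrics": m,
        "qc": result.qc_report,
        "segments": result.segments,
        "trees": result.trees,
    }


# ---------------------------------------------------------------------------
# validation battery


def _tube_truth(radius=2.0, half_len=30.0, axes=(40, 10, 10)):
    pts = np.stack([np.linspace(-half_len, half_len, 121),
                    np.zeros(121), np.zeros(121)], axis=1)
    seg = SegmentTruth(points=pts, radius_mm=radius, tree_id=0,
                       compartment="vein", arc_mm=2 * half_len,
                       chord_mm=2 * half_len, distance_metric=1.0)
    return PhantomTruth(segments=[seg], airways=[], lung_axes=axes,
                        lung_centre=np.zeros(3), lung_volume_l=0.02)


def _measure_single(truth, spacing=0.5, seed=0, noise=20.0):
    spec = PhantomSpec(lung_axes=truth.lung_axes, spacing=(spacing,) * 3,
                       noise_sd=noise, seed=seed, vessel_volume_fraction=None)
    vol, masks = rasterize(truth, spec)
    field = vessel_extract.compute_vesselness(
        preprocess.median_prefilter(vol), masks["lung"], intensity=vol)
    paths = vessel_extract.extract_paths(field)
    trees = vessel_extract.build_trees(
        paths, vol.spacing, junctions=vessel_extract.detect_junctions(field),
        field=field)
    return trees


def run_validation_suite(config: RunConfig | None = None) -> dict:
    """The phantom battery: straight tube, circular arcs, Y-tree.

    Returns a report dict with per-item pass/fail and measured values.
    """
    cfg = config or RunConfig()
    report = {}

    trees = _measure_single(_tube_truth(), seed=cfg.seed % (2 ** 31))
    dms = [s.distance_metric for t in trees for s in t.segments]
    report["straight_tube"] = {
        "dm": dms, "pass": len(dms) == 1 and abs(dms[0] - 1.0) <= 0.005}

    half = make_arc_segment(15.0, np.pi, tube_radius_mm=2.0,
                            centre=(0, -7.5, 0))
    t = PhantomTruth(segments=[half], airways=[], lung_axes=(25, 18, 10),
                     lung_centre=np.zeros(3), lung_volume_l=0.02)
    trees = _measure_single(t, seed=(cfg.seed + 1) % (2 ** 31))
    dms = [s.distance_metric for t2 in trees for s in t2.segments]
    report["half_circle"] = {
        "dm": dms, "expected": float(np.pi / 2),
        "pass": len(dms) == 1 and abs(dms[0] - np.pi / 2) <= 0.01}

    quarter = make_arc_segment(20.0, np.pi / 2, tube_radius_mm=2.0,
                               centre=(-10, -10, 0))
    t = PhantomTruth(segments=[quarter], airways=[], lung_axes=(21, 21, 10),
                     lung_centre=np.zeros(3), lung_volume_l=0.02)
    trees = _measure_single(t, seed=(cfg.seed + 2) % (2 ** 31))
    dms = [s.distance_metric for t2 in trees for s in t2.segments]
    report["quarter_circle"] = {
        "dm": dms, "expected": 1.1107,
        "pass": len(dms) == 1 and abs(dms[0] - 1.1107) <= 0.01}

    report["y_tree"] = _validate_y(cfg)
    report["pass"] = all(v["pass"] for v in report.values()
                         if isinstance(v, dict))
    return report


def _y_truth():
    import math as _m

    def line(a, b, n=80):
        t = np.linspace(0, 1, n)[:, None]
        return np.asarray(a, float) + t * (np.asarray(b, float)
                                           - np.asarray(a, float))

    def seg(points, r):
        arc = float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))
        chord = float(np.linalg.norm(points[-1] - points[0]))
        return SegmentTruth(points=points, radius_mm=r, tree_id=0,
                            compartment="vein", arc_mm=arc, chord_mm=chord,
                            distance_metric=arc / chord)

    ang = _m.radians(35)
    parent = seg(line([-25, 0, 0], [0, 0, 0]), 2.2)
    d1 = seg(line([0, 0, 0], [20 * _m.cos(ang), 20 * _m.sin(ang), 0]), 1.8)
    d2 = seg(line([0, 0, 0], [20 * _m.cos(ang), -20 * _m.sin(ang), 0]), 1.8)
    return PhantomTruth(segments=[parent, d1, d2], airways=[],
                        lung_axes=(34, 20, 10), lung_centre=np.zeros(3),
                        lung_volume_l=0.03)


def _validate_y(cfg: RunConfig) -> dict:
    trees = _measure_single(_y_truth(), spacing=0.7,
                            seed=cfg.seed % (2 ** 31))
    n_trees = len(trees)
    n_segs = sum(len(t.segments) for t in trees)
    n_bif = sum(t.n_bifurcations for t in trees)
    return {"n_trees": n_trees, "n_segments": n_segs,
            "n_bifurcations": n_bif,
            "pass": n_trees == 1 and n_segs == 3 and n_bif == 1}
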