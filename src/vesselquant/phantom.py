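"""Synthetic CT phantoms with analytically known vascular geometry.

The generator builds an ellipsoidal "lung" filled with recursive binary
vessel trees.  Each vessel segment is a straight chord plus a single
half-period sinusoidal transverse perturbation; its arc length, chord and
distance metric (DM = arc/chord, the tortuosity measure) are computed from
the generative curve by quadrature, never from the raster.  For a relative
amplitude ``a`` the DM depends only on ``a``::

    DM(a) = \int_0^1 sqrt(1 + (a*pi*cos(pi t))^2) dt

which is inverted by 1-D root finding so that per-segment target DM values
drawn from a shifted-lognormal distribution (median and 15th-85th
percentile width are the controls) are hit exactly in the ground truth.

Arterial trees carry a parallel "airway" tube at a fixed offset of
1.5 vessel radii, the minimum structure needed by the bronchus-proximity
artery/vein rule.  A cohort generator draws per-subject metric vectors and
pulmonary-function values linked by an explicit linear model.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .image_io import CtVolume, LabelMask

# z-score of the 85th percentile, used to map a P85-P15 width onto the
# lognormal shape parameter
_Z85 = 1.0364333894937898


# ---------------------------------------------------------------------------
# specs


@dataclass
class PhantomSpec:
    """Parameters of one synthetic thoracic volume.

    Defaults emulate a reduced (~0.5 L) lung at 0.7 mm isotropic
    resolution whose vessel population matches the cohort summary used
    throughout: ~362 segments/L, median DM 1.029, DM width 0.058, total
    vessel volume 3.6% of lung volume (set ``vessel_volume_fraction``).
    """

    grid_shape: Optional[tuple] = None       # voxels per axis; None = fit lung
    spacing: tuple = (0.7, 0.7, 0.7)         # mm
    lung_axes: tuple = (60.0, 50.0, 40.0)    # ellipsoid semi-axes, mm (~0.5 L)
    n_trees: int = 13
    segments_per_tree: tuple = (14, 14)      # inclusive range
    radius_range: tuple = (1.15, 1.95)       # mm (segment radii at generation)
    tortuosity_amplitude: Optional[float] = None  # fixed relative amplitude;
                                             # None = draw per-segment DM targets
    dm_median: float = 1.029                 # target median distance metric
    dm_spread: float = 0.058                 # target P85 - P15 of DM
    vessel_volume_fraction: Optional[float] = 0.036  # calibrate radii to this
    artery_fraction: float = 0.583           # proportion of trees arterial
    airway_offset_radii: float = 1.5         # airway centreline offset, in vessel radii
    airway_radius_ratio: float = 0.45        # airway radius / vessel radius
    hu_levels: dict = field(default_factory=lambda: {
        "vessel": 50.0, "parenchyma": -850.0,
        "airway_lumen": -1000.0, "background": -1024.0})
    noise_sd: float = 20.0                   # HU
    partial_volume_sigma: float = 0.5        # voxels; 0 disables smoothing
    margin_mm: float = 8.0                   # grid margin around the lung
    base_length_mm: float = 20.0             # root segment length
    length_decay: float = 0.93
    min_length_mm: float = 10.0
    radius_decay: float = 0.90
    calibration_radius_floor_mm: float = 1.08  # radii never calibrated below this
    cone_half_angle_deg: float = 40.0
    clearance_mm: float = 1.5                # gap between tube envelopes
    max_attempts: int = 80
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.radius_range[0] <= 0:
            raise ValueError("radii must be positive")
        if not 0.0 <= self.artery_fraction <= 1.0:
            raise ValueError("artery_fraction must be in [0, 1]")
        if self.radius_range[0] > min(self.lung_axes):
            raise ValueError("vessel radius exceeds the lung semi-axis")

    @property
    def lung_volume_l(self) -> float:
        a, b, c = self.lung_axes
        return 4.0 / 3.0 * math.pi * a * b * c / 1.0e6

    def resolved_grid_shape(self) -> tuple:
        if self.grid_shape is not None:
            return tuple(int(n) for n in self.grid_shape)
        ext = 2.0 * (np.asarray(self.lung_axes) + self.margin_mm)
        return tuple(int(math.ceil(e / s)) for e, s in zip(ext, self.spacing))


@dataclass
class SegmentTruth:
    """Generative ground truth for one vessel segment."""

    points: np.ndarray          # (M, 3) ordered centreline, world mm
    radius_mm: float
    tree_id: int
    compartment: str            # "artery" | "vein"
    arc_mm: float               # analytic, from the generative curve
    chord_mm: float
    distance_metric: float
    depth: int = 0

    @property
    def volume_ml(self) -> float:
        return math.pi * self.radius_mm ** 2 * self.arc_mm / 1.0e3


@dataclass
class PhantomTruth:
    """All generative structures of one phantom, in world coordinates."""

    segments: list
    airways: list               # list of (points (M,3), radius_mm)
    lung_axes: tuple
    lung_centre: np.ndarray
    lung_volume_l: float        # analytic ellipsoid volume

    def segment_frame(self) -> pd.DataFrame:
        rows = [{
            "tree_id": s.tree_id, "label": s.compartment,
            "arc_mm": s.arc_mm, "chord_mm": s.chord_mm,
            "distance_metric": s.distance_metric,
            "mean_radius_mm": s.radius_mm,
            "volume_ml": s.volume_ml,
        } for s in self.segments]
        return pd.DataFrame(rows)

    @property
    def total_vessel_volume_ml(self) -> float:
        return float(sum(s.volume_ml for s in self.segments))


# ---------------------------------------------------------------------------
# amplitude <-> distance-metric map


def dm_for_amplitude(a: float) -> float:
    """Distance metric of a chord with half-sine transverse perturbation
    of relative amplitude ``a`` (independent of chord length)."""
    if a == 0.0:
        return 1.0
    val, _ = quad(lambda t: math.hypot(1.0, a * math.pi * math.cos(math.pi * t)),
                  0.0, 1.0, limit=200)
    return val


def amplitude_for_dm(dm: float) -> float:
    """Invert :func:`dm_for_amplitude` by bracketing root finding."""
    if dm < 1.0:
        raise ValueError("distance metric must be >= 1")
    if dm == 1.0:
        return 0.0
    hi = 0.1
    while dm_for_amplitude(hi) < dm:
        hi *= 2.0
        if hi > 1e3:
            raise ValueError(f"unattainable distance metric {dm}")
    return brentq(lambda a: dm_for_amplitude(a) - dm, 0.0, hi, xtol=1e-12)


def dm_lognormal_sigma(median: float, spread: float) -> float:
    """Shape parameter of the shifted-lognormal DM model with the given
    median and 15th-85th percentile width."""
    m = median - 1.0
    if m <= 0:
        if spread > 0:
            raise ValueError("median DM must exceed 1 when spread > 0")
        return 0.0
    return math.asinh(spread / (2.0 * m)) / _Z85


def sample_dm_targets(rng, n: int, median: float, spread: float) -> np.ndarray:
    sigma = dm_lognormal_sigma(median, spread)
    m = max(median - 1.0, 0.0)
    if m == 0.0 or sigma == 0.0:
        return np.full(n, median)
    return 1.0 + m * np.exp(sigma * rng.standard_normal(n))


# ---------------------------------------------------------------------------
# curve construction


def _unit(v):
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def _perp_basis(d):
    """Two unit vectors orthogonal to d."""
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(d, ref))
    v = np.cross(d, u)
    return u, v


def sine_curve(start, end, amplitude_rel, normal, n_points=None, step_mm=0.5):
    """Sample the half-sine perturbed chord from ``start`` to ``end``."""
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    chord = float(np.linalg.norm(end - start))
    if n_points is None:
        n_points = max(int(math.ceil(chord / step_mm)) + 1, 9)
    t = np.linspace(0.0, 1.0, n_points)
    pts = start[None, :] + t[:, None] * (end - start)[None, :]
    pts = pts + (amplitude_rel * chord * np.sin(math.pi * t))[:, None] * normal[None, :]
    return pts


def make_arc_segment(radius_mm, angle_rad, tube_radius_mm=2.0, centre=(0, 0, 0),
                     plane=("x", "y"), n_points=200, tree_id=0,
                     compartment="vein") -> SegmentTruth:
    """A circular-arc control segment with closed-form DM.

    The DM of a circular arc subtending ``angle_rad`` is
    ``(angle/2) / sin(angle/2)``: pi/2 for a half circle, ~1.1107 for a
    quarter circle.
    """
    theta = np.linspace(0.0, angle_rad, n_points)
    pts = np.tile(np.asarray(centre, float), (n_points, 1))
    axes = {"x": 0, "y": 1, "z": 2}
    i, j = axes[plane[0]], axes[plane[1]]
    pts[:, i] += radius_mm * np.cos(theta)
    pts[:, j] += radius_mm * np.sin(theta)
    arc = radius_mm * angle_rad
    chord = 2.0 * radius_mm * math.sin(angle_rad / 2.0)
    return SegmentTruth(points=pts, radius_mm=tube_radius_mm, tree_id=tree_id,
                        compartment=compartment, arc_mm=arc, chord_mm=chord,
                        distance_metric=arc / chord)


def _polyline_inside_ellipsoid(pts, axes, centre, margin):
    ax = np.asarray(axes) - margin
    if np.any(ax <= 0):
        return False
    q = (pts - centre) / ax
    return bool(np.all(np.sum(q * q, axis=1) <= 1.0))


# ---------------------------------------------------------------------------
# tree generation


class _Occupancy:
    """Accumulated centreline samples with effective envelope radii, for
    collision tests between tubes (vessel + its airway, if any)."""

    def __init__(self):
        self.points = np.zeros((0, 3))
        self.radii = np.zeros(0)
        self.tree_ids = np.zeros(0, dtype=int)
        self._tree = None

    def add(self, pts, eff_radius, tree_id=-1):
        self.points = np.vstack([self.points, pts])
        self.radii = np.concatenate([self.radii, np.full(len(pts), eff_radius)])
        self.tree_ids = np.concatenate([self.tree_ids,
                                        np.full(len(pts), tree_id, dtype=int)])
        self._tree = None

    def checkpoint(self):
        return len(self.radii)

    def rollback(self, mark):
        self.points = self.points[:mark]
        self.radii = self.radii[:mark]
        self.tree_ids = self.tree_ids[:mark]
        self._tree = None

    def clear_of(self, pts, eff_radius, clearance, exclude_centre=None,
                 exclude_radius=0.0, same_tree=None):
        """True if every point of ``pts`` keeps envelope clearance from all
        stored samples.  Samples of the *same tree* near ``exclude_centre``
        (the shared junction with parent and sibling) are ignored; other
        trees must keep clearance everywhere."""
        if len(self.points) == 0:
            return True
        if self._tree is None:
            self._tree = cKDTree(self.points)
        rmax = float(self.radii.max())
        limit = eff_radius + rmax + clearance
        idx_lists = self._tree.query_ball_point(pts, limit)
        for p, idxs in zip(pts, idx_lists):
            if not idxs:
                continue
            for k in idxs:
                q = self.points[k]
                if exclude_centre is not None and \
                        (same_tree is None or self.tree_ids[k] == same_tree) \
                        and np.linalg.norm(q - exclude_centre) < exclude_radius:
                    continue
                if np.linalg.norm(p - q) < eff_radius + self.radii[k] + clearance:
                    return False
        return True


def _eff_radius(spec: PhantomSpec, r: float, arterial: bool) -> float:
    """Envelope radius of a vessel including its paired airway tube."""
    if arterial:
        return r * (spec.airway_offset_radii + spec.airway_radius_ratio)
    return r


def generate_tree(spec: PhantomSpec, tree_index: int,
                  occupancy: Optional[_Occupancy] = None,
                  root: Optional[np.ndarray] = None,
                  arterial: bool = False) -> list:
    """Grow one rooted binary tree of :class:`SegmentTruth` inside the lung.

    Growth is breadth-first: each accepted segment enqueues two children
    whose directions are drawn within a cone around the parent direction,
    lengths and radii decaying per generation.  A candidate segment is
    rejected (and re-drawn, up to ``spec.max_attempts`` times) if it leaves
    the lung ellipsoid or violates tube clearance against previously placed
    structures; unplaceable branches are skipped, and the whole call raises
    if not a single segment can be placed.
    """
    rng = np.random.default_rng([spec.seed, 1000 + tree_index])
    occupancy = occupancy if occupancy is not None else _Occupancy()
    lo, hi = spec.segments_per_tree
    n_target = int(rng.integers(lo, hi + 1))
    centre = np.zeros(3)
    axes = np.asarray(spec.lung_axes, float)
    r_lo, r_hi = spec.radius_range
    root_radius = float(rng.uniform(r_lo + 0.7 * (r_hi - r_lo), r_hi))
    compartment = "artery" if arterial else "vein"

    # retry over root placements until the tree reaches its target size;
    # a partially grown attempt is rolled back before the next root draw
    best: list[SegmentTruth] = []
    for root_attempt in range(30):
        if root is not None and root_attempt > 0:
            break
        if root is None:
            cand = centre + rng.uniform(-0.55, 0.55, 3) * axes
            if not _polyline_inside_ellipsoid(cand[None, :], axes, centre, 6.0):
                continue
            start_root = cand
        else:
            start_root = np.asarray(root, float)
        mark = occupancy.checkpoint()
        segs = _grow_from_root(spec, rng, occupancy, start_root, root_radius,
                               n_target, tree_index, compartment, arterial)
        if len(segs) >= n_target or (root is not None and segs):
            return segs
        if len(segs) > len(best):
            best = segs
        occupancy.rollback(mark)

    if best:
        # re-commit the best attempt's footprint
        for s in best:
            occupancy.add(s.points, _eff_radius(spec, s.radius_mm, arterial),
                          tree_index)
        return best
    raise RuntimeError(f"failed to place any segment for tree {tree_index}")


def _grow_from_root(spec, rng, occupancy, root, root_radius, n_target,
                    tree_index, compartment, arterial):
    axes = np.asarray(spec.lung_axes, float)
    r_lo, r_hi = spec.radius_range
    root_dir = _unit(rng.standard_normal(3))
    segments: list[SegmentTruth] = []
    queue = deque([(np.asarray(root, float), root_dir, root_radius, 0)])
    cone = math.radians(spec.cone_half_angle_deg)

    while queue and len(segments) < n_target:
        start, pdir, radius, depth = queue.popleft()
        radius = float(np.clip(radius, r_lo, r_hi))
        length = max(spec.base_length_mm * spec.length_decay ** depth,
                     spec.min_length_mm)
        if spec.tortuosity_amplitude is not None:
            amp = float(spec.tortuosity_amplitude)
            dm = dm_for_amplitude(amp)
        else:
            dm = float(sample_dm_targets(rng, 1, spec.dm_median, spec.dm_spread)[0])
            amp = amplitude_for_dm(dm)
        eff_r = _eff_radius(spec, radius, arterial)

        placed = False
        for _ in range(spec.max_attempts):
            # direction within a cone around the parent direction
            ang = rng.uniform(0.35 * cone, cone)
            u, v = _perp_basis(pdir)
            phi = rng.uniform(0, 2 * math.pi)
            d = _unit(math.cos(ang) * pdir
                      + math.sin(ang) * (math.cos(phi) * u + math.sin(phi) * v))
            end = start + length * d * rng.uniform(0.85, 1.15)
            nu, nv = _perp_basis(_unit(end - start))
            psi = rng.uniform(0, 2 * math.pi)
            normal = math.cos(psi) * nu + math.sin(psi) * nv
            pts = sine_curve(start, end, amp, normal)
            if not _polyline_inside_ellipsoid(pts, axes, np.zeros(3), eff_r + 1.0):
                continue
            # skip the first quarter of the curve in the clearance test: it
            # legitimately sits next to the parent and sibling near the fork
            probe = pts[len(pts) // 4:]
            if not occupancy.clear_of(probe, eff_r, spec.clearance_mm,
                                      exclude_centre=start,
                                      exclude_radius=4.0 * radius + 4.0,
                                      same_tree=tree_index):
                continue
            placed = True
            break
        if not placed:
            continue

        chord = float(np.linalg.norm(end - start))
        seg = SegmentTruth(points=pts, radius_mm=radius, tree_id=tree_index,
                           compartment=compartment, arc_mm=chord * dm,
                           chord_mm=chord, distance_metric=dm, depth=depth)
        segments.append(seg)
        occupancy.add(pts, eff_r, tree_index)
        child_r = radius * spec.radius_decay
        end_dir = _unit(pts[-1] - pts[-2])
        queue.append((pts[-1].copy(), end_dir, child_r, depth + 1))
        queue.append((pts[-1].copy(), end_dir, child_r, depth + 1))

    return segments


def _prune_leaves(segs, keep):
    """Drop deepest segments first so a tree can be truncated to ``keep``
    segments while remaining a connected rooted tree."""
    order = sorted(range(len(segs)), key=lambda i: (segs[i].depth, i))
    return [segs[i] for i in sorted(order[:keep])]


def _calibrate_radii(segments, spec: PhantomSpec):
    """Rescale radii by one global factor so summed tube volume equals
    ``vessel_volume_fraction`` of the analytic lung volume; radii are never
    pushed below the calibration floor (the rest re-scales to conserve the
    total), so every tube stays above the 2 mm diameter gate."""
    target_ml = spec.vessel_volume_fraction * spec.lung_volume_l * 1.0e3
    floor = spec.calibration_radius_floor_mm
    base = np.array([s.radius_mm for s in segments])
    arcs = np.array([s.arc_mm for s in segments])
    scale = math.sqrt(target_ml * 1.0e3 / float(np.sum(math.pi * base ** 2 * arcs)))
    if not 0.4 <= scale <= 2.5:
        raise RuntimeError(
            f"radius calibration factor {scale:.3f} out of range; adjust "
            "radius_range or vessel_volume_fraction")
    new = np.maximum(base * scale, floor)
    for _ in range(25):
        clipped = new <= floor
        vol_clipped = float(np.sum(math.pi * new[clipped] ** 2 * arcs[clipped]))
        free = ~clipped
        if not free.any() or target_ml * 1e3 <= vol_clipped:
            break
        s2 = math.sqrt((target_ml * 1e3 - vol_clipped)
                       / float(np.sum(math.pi * (base[free] * scale) ** 2 * arcs[free])))
        new[free] = np.maximum(base[free] * scale * s2, floor)
        if abs(s2 - 1.0) < 1e-9:
            break
    for s, r in zip(segments, new):
        s.radius_mm = float(r)


def _airway_for_segment(spec: PhantomSpec, seg: SegmentTruth, offset_dir):
    """Parallel airway tube beside an arterial segment: the centreline is
    offset perpendicular to the segment chord by 1.5 vessel radii."""
    d = _unit(seg.points[-1] - seg.points[0])
    perp = offset_dir - np.dot(offset_dir, d) * d
    if np.linalg.norm(perp) < 1e-6:
        perp, _ = _perp_basis(d)
    perp = _unit(perp)
    offset = spec.airway_offset_radii * seg.radius_mm * perp
    return seg.points + offset[None, :], spec.airway_radius_ratio * seg.radius_mm


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate the full phantom ground truth: all trees plus airways.

    If ``spec.vessel_volume_fraction`` is set, all radii are rescaled by a
    single analytic factor so that the summed tube volume equals that
    fraction of the (analytic) lung volume; the rescaled radii must stay
    within ``radius_range`` stretched by a factor 2 or the call raises.
    """
    rng = np.random.default_rng([spec.seed, 7])
    occupancy = _Occupancy()
    n_art = int(round(spec.artery_fraction * spec.n_trees))
    order = rng.permutation(spec.n_trees)
    arterial_flags = [t in set(order[:n_art].tolist())
                      for t in range(spec.n_trees)]
    target_total = int(round(spec.n_trees * 0.5 * sum(spec.segments_per_tree)))

    segments: list[SegmentTruth] = []
    arterial_by_tree = {}
    t = 0
    # grow trees until the target segment count is reached; placement
    # failures in a crowded lung are compensated by extra (top-up) trees
    while len(segments) < target_total and t < 3 * spec.n_trees:
        arterial = arterial_flags[t] if t < spec.n_trees else \
            (len([1 for a in arterial_by_tree.values() if a])
             < spec.artery_fraction * (len(arterial_by_tree) + 1))
        segs = generate_tree(spec, t, occupancy=occupancy, arterial=arterial)
        if len(segments) + len(segs) > target_total:
            segs = _prune_leaves(segs, target_total - len(segments))
        segments.extend(segs)
        arterial_by_tree[t] = arterial
        t += 1

    if spec.vessel_volume_fraction is not None:
        _calibrate_radii(segments, spec)

    airways = []
    for t, arterial in sorted(arterial_by_tree.items()):
        if not arterial:
            continue
        offset_dir = _unit(np.random.default_rng([spec.seed, 13, t]).standard_normal(3))
        for s in segments:
            if s.tree_id == t:
                airways.append(_airway_for_segment(spec, s, offset_dir))

    return PhantomTruth(segments=segments, airways=airways,
                        lung_axes=tuple(spec.lung_axes),
                        lung_centre=np.zeros(3),
                        lung_volume_l=spec.lung_volume_l)


# ---------------------------------------------------------------------------
# rasterization


def _paint_tube(hu_or_mask_list, pts, radius_mm, spacing, origin, shape):
    """Set mask voxels whose centre lies within ``radius_mm`` of the
    polyline.  Operates on a bounding box only."""
    spacing = np.asarray(spacing)
    lo_w = pts.min(axis=0) - radius_mm - spacing
    hi_w = pts.max(axis=0) + radius_mm + spacing
    lo = np.maximum(np.floor((lo_w - origin) / spacing - 0.5).astype(int), 0)
    hi = np.minimum(np.ceil((hi_w - origin) / spacing - 0.5).astype(int) + 1,
                    np.asarray(shape))
    if np.any(lo >= hi):
        return
    # densify the polyline so the sample spacing is < half a voxel
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    step = 0.4 * float(spacing.min())
    dense = [pts[0]]
    for a, b, L in zip(pts[:-1], pts[1:], seglen):
        n = max(int(math.ceil(L / step)), 1)
        tt = np.linspace(0, 1, n + 1)[1:]
        dense.append(a[None, :] + tt[:, None] * (b - a)[None, :])
    dense = np.vstack([dense[0][None, :]] + dense[1:])
    tree = cKDTree(dense)
    ii = [np.arange(lo[k], hi[k]) for k in range(3)]
    gx, gy, gz = np.meshgrid(*ii, indexing="ij")
    centres = origin + (np.stack([gx, gy, gz], axis=-1) + 0.5) * spacing
    ramp = float(np.min(spacing))
    d, _ = tree.query(centres.reshape(-1, 3), k=1,
                      distance_upper_bound=radius_mm + ramp)
    d = d.reshape(gx.shape)
    inside = d <= radius_mm
    # anti-aliased coverage: linear ramp over one voxel across the surface,
    # so sub-voxel tube cross-sections carry true partial-volume fractions
    cover = np.clip((radius_mm - d) / ramp + 0.5, 0.0, 1.0)
    for arr in hu_or_mask_list:
        sub = arr[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        if arr.dtype == np.uint8:
            sub[inside] = 1
        else:
            np.maximum(sub, cover.astype(arr.dtype), out=sub)
        arr[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sub


def rasterize(truth: PhantomTruth, spec: PhantomSpec):
    """Render the phantom to a HU volume plus aligned label masks.

    Returns ``(CtVolume, masks)`` where ``masks`` is a dict with binary
    LabelMasks under keys ``lung, airway, vessel, artery, vein``.  Raises
    if any tube is narrower than one voxel (unresolvable at this spacing).
    """
    spacing = np.asarray(spec.spacing, float)
    shape = spec.resolved_grid_shape()
    origin = -0.5 * spacing * np.asarray(shape)  # lung centred at world 0

    min_diam = min([2 * s.radius_mm for s in truth.segments]
                   + [2 * r for _, r in truth.airways] or [np.inf])
    if min_diam < float(spacing.max()):
        raise ValueError(
            f"tube diameter {min_diam:.2f} mm is below one voxel "
            f"({spacing.max():.2f} mm); refine the grid or fatten the tube")

    # lung ellipsoid on voxel centres
    coords = [origin[k] + (np.arange(shape[k]) + 0.5) * spacing[k]
              for k in range(3)]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    ax = np.asarray(truth.lung_axes)
    c = truth.lung_centre
    lung = (((gx - c[0]) / ax[0]) ** 2 + ((gy - c[1]) / ax[1]) ** 2
            + ((gz - c[2]) / ax[2]) ** 2) <= 1.0
    del gx, gy, gz

    vessel = np.zeros(shape, dtype=np.uint8)
    artery = np.zeros(shape, dtype=np.uint8)
    vein = np.zeros(shape, dtype=np.uint8)
    airway = np.zeros(shape, dtype=np.uint8)
    vessel_frac = np.zeros(shape, dtype=np.float32)
    airway_frac = np.zeros(shape, dtype=np.float32)

    for pts, r in truth.airways:
        _paint_tube([airway, airway_frac], pts, r, spacing, origin, shape)
    for s in truth.segments:
        targets = [vessel, vessel_frac,
                   artery if s.compartment == "artery" else vein]
        _paint_tube(targets, s.points, s.radius_mm, spacing, origin, shape)
    airway[vessel > 0] = 0  # vessels win contested voxels
    airway_frac[vessel_frac >= 1.0] = 0.0

    levels = spec.hu_levels
    hu = np.full(shape, levels["background"], dtype=np.float32)
    hu[lung] = levels["parenchyma"]
    hu = hu * (1 - airway_frac) + airway_frac * levels["airway_lumen"]
    hu = hu * (1 - vessel_frac) + vessel_frac * levels["vessel"]

    if spec.partial_volume_sigma > 0:
        hu = gaussian_filter(hu, spec.partial_volume_sigma)
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, 999])
        hu = hu + rng.normal(0.0, spec.noise_sd, size=hu.shape).astype(np.float32)

    vol = CtVolume(values=hu.astype(np.float32), spacing=spacing, origin=origin)
    masks = {
        "lung": LabelMask(lung.astype(np.uint8), spacing, origin),
        "airway": LabelMask(airway, spacing, origin),
        "vessel": LabelMask(vessel, spacing, origin),
        "artery": LabelMask(artery, spacing, origin),
        "vein": LabelMask(vein, spacing, origin),
    }
    return vol, masks


# ---------------------------------------------------------------------------
# synthetic cohorts


@dataclass
class PftLink:
    """One pulmonary-function variable generated as a linear combination of
    metrics plus Gaussian noise.  Either ``noise_sd`` is given directly or
    it is derived from ``target_r2`` (population R^2 of the linear signal)."""

    betas: dict                     # metric column -> coefficient
    mean: float                     # population mean of the PFT
    target_r2: Optional[float] = None
    noise_sd: Optional[float] = None

    def __post_init__(self):
        if (self.target_r2 is None) == (self.noise_sd is None):
            raise ValueError("give exactly one of target_r2 or noise_sd")
        if self.target_r2 is not None and not 0.0 < self.target_r2 <= 1.0:
            raise ValueError(f"unattainable target R^2: {self.target_r2}")


#: cohort summary used for defaults: metric -> (mean, sd, lower bound)
DEFAULT_METRICS = {
    "normalized_vessel_volume_pct": (3.6, 0.8, 0.0),
    "vessel_density_per_l": (361.5, 106.1, 0.0),
    "vessel_tortuosity": (1.029, 0.003, 1.0),
    "vessel_heterogeneity": (0.058, 0.006, 0.0),
    "total_lung_volume_l": (3.9, 1.1, 0.0),
}

#: default metric-metric correlations (volume couples with density,
#: tortuosity with heterogeneity; other pairs uncorrelated)
DEFAULT_CORRELATIONS = {
    ("normalized_vessel_volume_pct", "vessel_density_per_l"): 0.9,
    ("vessel_tortuosity", "vessel_heterogeneity"): 0.9,
}


def _default_pft_links():
    return {
        "fev1_pct_pred": PftLink({"normalized_vessel_volume_pct": -8.27},
                                 mean=73.7, target_r2=0.12),
        "fvc_pct_pred": PftLink({"normalized_vessel_volume_pct": -13.14},
                                mean=72.7, target_r2=0.27),
        "dlco_pct_pred": PftLink({"normalized_vessel_volume_pct": -5.58,
                                  "vessel_heterogeneity": -680.0},
                                 mean=38.9, target_r2=0.21),
        "kco_pct_pred": PftLink({}, mean=69.9, noise_sd=19.0),
        "tlc_pct_pred": PftLink({"normalized_vessel_volume_pct": -13.25},
                                mean=67.2, target_r2=0.45),
        "cpi": PftLink({"normalized_vessel_volume_pct": 7.66},
                       mean=52.2, target_r2=0.28),
    }


@dataclass
class CohortSpec:
    """Parameters of a synthetic subject cohort."""

    n_subjects: int = 152
    metrics: dict = field(default_factory=lambda: dict(DEFAULT_METRICS))
    correlations: dict = field(default_factory=lambda: dict(DEFAULT_CORRELATIONS))
    pft_links: dict = field(default_factory=_default_pft_links)
    male_fraction: float = 122.0 / 152.0
    smoking_p: tuple = (50 / 152, 100 / 152, 2 / 152)  # never/ever/current
    age_mean: float = 66.0
    age_sd: float = 9.0
    age_range: tuple = (38, 86)
    slice_thickness_levels: tuple = (0.7, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for name, (mu, sd, lo) in self.metrics.items():
            if sd < 0:
                raise ValueError(f"negative SD for metric {name}")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort table of metrics, PFTs and covariates.

    Metrics are sampled from a correlated Gaussian (resampling rows that
    violate physical bounds, so the moments stay close to the target), PFTs
    from the stated linear links, covariates from categorical/truncated
    distributions.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng([spec.seed, 31])
    names = list(spec.metrics.keys())
    mu = np.array([spec.metrics[n][0] for n in names])
    sd = np.array([spec.metrics[n][1] for n in names])
    lo = np.array([spec.metrics[n][2] for n in names])

    corr = np.eye(len(names))
    for (a, b), rho in spec.correlations.items():
        if a in names and b in names:
            ia, ib = names.index(a), names.index(b)
            corr[ia, ib] = corr[ib, ia] = rho
    cov = corr * np.outer(sd, sd)

    n = spec.n_subjects
    draws = np.zeros((n, len(names)))
    need = np.ones(n, dtype=bool)
    for _ in range(1000):
        k = int(need.sum())
        if k == 0:
            break
        cand = rng.multivariate_normal(mu, cov, size=k, method="cholesky")
        ok = np.all(cand > lo[None, :], axis=1)
        rows = np.flatnonzero(need)[:ok.sum()] if ok.sum() else []
        accepted = cand[ok][:len(rows)]
        draws[rows] = accepted
        need[rows] = False
    if need.any():
        raise RuntimeError("metric truncation bounds too tight to sample")

    df = pd.DataFrame(draws, columns=names)
    df.insert(0, "subject_id", [f"S{i:04d}" for i in range(n)])

    for pft, link in spec.pft_links.items():
        signal = np.zeros(n)
        var_signal = 0.0
        for m, beta in link.betas.items():
            signal += beta * (df[m].to_numpy() - spec.metrics[m][0])
            var_signal += (beta * spec.metrics[m][1]) ** 2
        # correlated metrics inflate/deflate the signal variance; use the
        # empirical variance so target R^2 is hit for the realised design
        if len(link.betas) > 1:
            var_signal = float(np.var(signal))
        if link.noise_sd is not None:
            noise_sd = link.noise_sd
        else:
            noise_sd = math.sqrt(var_signal * (1.0 / link.target_r2 - 1.0))
        df[pft] = link.mean + signal + rng.normal(0.0, noise_sd, n)

    age = rng.normal(spec.age_mean, spec.age_sd, n)
    df["age_years"] = np.clip(np.round(age), *spec.age_range).astype(int)
    df["male"] = (rng.random(n) < spec.male_fraction).astype(int)
    df["smoking_status"] = rng.choice(["never", "ever", "current"], size=n,
                                      p=np.asarray(spec.smoking_p) /
                                      sum(spec.smoking_p))
    df["slice_thickness_mm"] = rng.choice(spec.slice_thickness_levels, size=n)
    return df
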