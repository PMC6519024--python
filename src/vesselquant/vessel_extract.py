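"""Tube enhancement, sub-voxel centerline tracing and vessel-tree building.

The stage runs in four steps, all in world (mm) coordinates:

1. :func:`compute_vesselness` — multi-scale Hessian eigenvalue analysis
   (Frangi-type functional) giving a per-voxel tubularity response, a
   best-scale radius estimate and the local tube axis (the eigenvector of
   the smallest-magnitude eigenvalue).
2. :func:`extract_paths` — seeds at regularly spaced response maxima are
   traced bidirectionally along the orientation field with half-voxel
   steps; each point is re-centred onto the response ridge in the plane
   normal to the axis by parabolic refinement, and the tube radius is
   measured sub-voxel by half-contrast crossings along rays in that plane.
3. :func:`build_trees` — path endpoints landing on another path are fused
   into junction nodes, paths are split there, cycles broken, and each
   edge between adjacent nodes becomes one :class:`VesselSegment` with arc
   length, chord, distance metric (DM = arc/chord) and frustum volume.
4. :func:`filter_by_diameter` — only segments with mean diameter between
   2 and 10 mm (inclusive) are kept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
from scipy import ndimage

from .image_io import CtVolume, LabelMask

logger = logging.getLogger(__name__)

#: default filter scales (mm); cover tube radii ~1-5 mm
DEFAULT_SCALES_MM = (1.0, 1.5, 2.0, 3.0, 4.0, 5.0)

#: diameter gate (mm), inclusive bounds
MIN_DIAMETER_MM = 2.0
MAX_DIAMETER_MM = 10.0

FRANGI_ALPHA = 0.5
FRANGI_BETA = 0.5


# ---------------------------------------------------------------------------
# vesselness


@dataclass
class VesselnessField:
    """Per-voxel tubularity response with radius and axis estimates."""

    response: np.ndarray        # [0, 1], zero outside lung
    radius_mm: np.ndarray       # best-scale radius estimate
    orientation: np.ndarray     # (nx, ny, nz, 3) unit axis where response > 0
    spacing: np.ndarray
    origin: np.ndarray
    hu: Optional[np.ndarray] = None      # pre-filtered HU, for radius rays
    lung: Optional[np.ndarray] = None

    def index_to_world(self, idx):
        return self.origin + (np.asarray(idx, float) + 0.5) * self.spacing

    def world_to_index(self, xyz):
        return (np.asarray(xyz, float) - self.origin) / self.spacing - 0.5


def _hessian_at_scale(values, spacing, sigma_mm):
    """Scale-normalised Hessian (gamma = 2) of a 3-D image, mm units."""
    sig_vox = [sigma_mm / s for s in spacing]
    h = {}
    for (i, j) in [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]:
        order = [0, 0, 0]
        order[i] += 1
        order[j] += 1
        d = ndimage.gaussian_filter(values, sig_vox, order=order, mode="nearest")
        # gaussian_filter differentiates w.r.t. voxel index; convert to mm
        h[(i, j)] = d / (spacing[i] * spacing[j]) * sigma_mm ** 2
    return h


def compute_vesselness(vol: CtVolume, lung: LabelMask,
                       scales_mm=DEFAULT_SCALES_MM,
                       alpha: float = FRANGI_ALPHA, beta: float = FRANGI_BETA,
                       c: Optional[float] = None,
                       boundary_erosion_mm: float = 2.0,
                       intensity: Optional[CtVolume] = None) -> VesselnessField:
    """Multi-scale Frangi-type vesselness for bright tubes on dark ground.

    The response at each voxel is the maximum over scales; the radius
    estimate maps the argmax scale to a tube radius, and the orientation
    is the Hessian eigenvector of the smallest-magnitude eigenvalue at
    that scale.  ``c`` (structureness scale) defaults to half the maximum
    Frobenius norm per scale.
    """
    scales = sorted(float(s) for s in scales_mm)
    if len(scales) < 3:
        raise ValueError("need at least 3 scales")
    min_sp, max_sp = float(np.min(vol.spacing)), float(np.max(vol.spacing))
    if scales[0] < 0.5 * max_sp:
        raise ValueError(
            f"scale {scales[0]} mm not resolvable at spacing {max_sp} mm")

    lungmask = lung.values > 0
    vals = vol.values.astype(np.float32)

    # work inside the lung bounding box only
    idx = np.argwhere(lungmask)
    pad = int(math.ceil(scales[-1] / min_sp)) + 2
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, np.asarray(vol.shape))
    sub = tuple(slice(l, h) for l, h in zip(lo, hi))
    v = vals[sub]
    m = lungmask[sub]
    # distance to the lung boundary (mm): the pleural edge is a strong
    # bright-to-dark step that mimics a tube of radius ~sigma where it
    # curves, so each scale only responds deeper than sigma inside the lung
    dist_mm = ndimage.distance_transform_edt(m, sampling=vol.spacing)
    support = m & (dist_mm > boundary_erosion_mm)

    best_resp = np.zeros(v.shape, np.float32)
    best_rad = np.zeros(v.shape, np.float32)
    best_orient = np.zeros(v.shape + (3,), np.float32)

    for sigma in scales:
        H = _hessian_at_scale(v, vol.spacing, sigma)
        s2 = (H[(0, 0)] ** 2 + H[(1, 1)] ** 2 + H[(2, 2)] ** 2
              + 2 * (H[(0, 1)] ** 2 + H[(0, 2)] ** 2 + H[(1, 2)] ** 2))
        smax = float(np.sqrt(s2.max())) if s2.size else 0.0
        if smax == 0.0:
            continue
        cs = c if c is not None else 0.5 * smax
        # eigendecompose only where there is second-order structure, away
        # from the boundary by at least this scale's reach
        cand = m & (dist_mm > sigma + boundary_erosion_mm) \
            & (s2 > (0.02 * smax) ** 2)
        if not cand.any():
            continue
        ii = np.where(cand)
        Hm = np.empty((len(ii[0]), 3, 3), np.float32)
        for (a, b) in [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]:
            Hm[:, a, b] = H[(a, b)][ii]
            Hm[:, b, a] = H[(a, b)][ii]
        w, vecs = np.linalg.eigh(Hm)
        order = np.argsort(np.abs(w), axis=1)
        w = np.take_along_axis(w, order, axis=1)
        l1, l2, l3 = w[:, 0], w[:, 1], w[:, 2]
        a2, a3 = np.abs(l2), np.abs(l3)
        with np.errstate(divide="ignore", invalid="ignore"):
            ra = np.where(a3 > 0, a2 / a3, 0.0)
            rb = np.where(a2 * a3 > 0, np.abs(l1) / np.sqrt(a2 * a3), 0.0)
        s = np.sqrt(l1 ** 2 + l2 ** 2 + l3 ** 2)
        resp = ((1.0 - np.exp(-(ra ** 2) / (2 * alpha ** 2)))
                * np.exp(-(rb ** 2) / (2 * beta ** 2))
                * (1.0 - np.exp(-(s ** 2) / (2 * cs ** 2))))
        resp = np.where((l2 < 0) & (l3 < 0), resp, 0.0).astype(np.float32)

        upd = resp > best_resp[ii]
        if upd.any():
            axis_vec = np.take_along_axis(
                vecs, order[:, 0][:, None, None].repeat(3, axis=1), axis=2)[:, :, 0]
            flat = np.ravel_multi_index(ii, v.shape)
            sel = flat[upd]
            best_resp.ravel()[sel] = resp[upd]
            best_rad.ravel()[sel] = sigma * _RADIUS_PER_SCALE
            best_orient.reshape(-1, 3)[sel] = axis_vec[upd]

    response = np.zeros(vol.shape, np.float32)
    radius = np.zeros(vol.shape, np.float32)
    orientation = np.zeros(vol.shape + (3,), np.float32)
    support_full = np.zeros(vol.shape, bool)
    peak = float(best_resp.max())
    if peak > 0:
        response[sub] = best_resp / peak
        radius[sub] = best_rad
        orientation[sub] = best_orient
    support_full[sub] = support
    response[~support_full] = 0.0

    hu = intensity.values.astype(np.float32) if intensity is not None else vals
    return VesselnessField(response=response, radius_mm=radius,
                           orientation=orientation, spacing=vol.spacing,
                           origin=vol.origin, hu=hu, lung=support_full)


#: map from argmax Gaussian scale (sigma, mm) to tube radius (mm) for a
#: solid cylinder under gamma=2 normalisation; near 1 empirically
_RADIUS_PER_SCALE = 1.0


# ---------------------------------------------------------------------------
# path tracing


@dataclass
class CenterlinePath:
    points: np.ndarray          # (M, 3) world mm
    radii: np.ndarray           # (M,)
    responses: np.ndarray       # (M,)
    hit_start: Optional[int] = None   # path id whose territory ended the trace
    hit_end: Optional[int] = None

    def __post_init__(self):
        if len(self.points) < 2:
            raise ValueError("a path needs at least 2 points")

    @property
    def arc_mm(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


def _interp(arr, frac_idx):
    return float(ndimage.map_coordinates(
        arr, np.asarray(frac_idx, float).reshape(3, 1), order=1,
        mode="nearest")[0])


def _interp_many(arr, frac_idx):
    return ndimage.map_coordinates(arr, np.asarray(frac_idx, float).T,
                                   order=1, mode="nearest")


def _perp_basis(d):
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(d, u)


def _parabolic_offset(rm, r0, rp, delta):
    den = rm - 2.0 * r0 + rp
    if den >= -1e-12:       # not a maximum
        return 0.0
    off = 0.5 * delta * (rm - rp) / den
    return float(np.clip(off, -delta, delta))


class _Tracer:
    """Stateful ridge tracer over one vesselness field."""

    def __init__(self, field: VesselnessField, trace_threshold: float,
                 step_mm: float, claim_factor: float = 1.0,
                 max_steps: int = 4000):
        self.f = field
        self.thr = trace_threshold
        self.h = step_mm
        self.claim_factor = claim_factor
        self.max_steps = max_steps
        self.claim = np.full(field.response.shape, -1, np.int32)
        self.shape = np.asarray(field.response.shape)
        self.min_sp = float(np.min(field.spacing))
        # effective blur of the intensity grid (acquisition + raster)
        self.pv_sigma = 0.6 * self.min_sp

    # -- sampling helpers ---------------------------------------------------

    def _voxel(self, p):
        idx = np.rint(self.f.world_to_index(p)).astype(int)
        if np.any(idx < 0) or np.any(idx >= self.shape):
            return None
        return tuple(idx)

    def response_at(self, p):
        return _interp(self.f.response, self.f.world_to_index(p))

    def recenter(self, p, d, iters=2):
        """Shift p onto the response ridge in the plane normal to d."""
        delta = 0.5 * self.min_sp
        for _ in range(iters):
            u, v = _perp_basis(d)
            offs = np.array([[0, 0], [-1, 0], [1, 0], [0, -1], [0, 1]], float) * delta
            pts = p[None, :] + offs[:, 0:1] * u[None, :] + offs[:, 1:2] * v[None, :]
            r = _interp_many(self.f.response, self.f.world_to_index(pts))
            du = _parabolic_offset(r[1], r[0], r[2], delta)
            dv = _parabolic_offset(r[3], r[0], r[4], delta)
            p = p + du * u + dv * v
        return p

    def radius_at(self, p, d, r_init, n_rays=8, min_contrast_hu=300.0,
                  return_offset=False):
        """Tube radius in the plane normal to d by half-contrast crossings.

        For thin tubes the centre intensity is attenuated by the blur of
        acquisition/rasterisation, which drags the naive half level (and
        with it the crossing) inward; the estimate is therefore iterated
        with an analytic plateau correction for a blurred disk,
        A = 1 - exp(-r^2 / 2 sigma^2).  Returns NaN when the local
        contrast is too weak for a reliable boundary."""
        r_max = max(3.0 * r_init, 2.0) + 1.0
        step = 0.25 * self.min_sp
        radii = np.arange(0.0, r_max + step, step)
        u, v = _perp_basis(d)
        angles = np.arange(n_rays) * (2 * math.pi / n_rays)
        dirs = np.outer(np.cos(angles), u) + np.outer(np.sin(angles), v)
        pts = (p[None, None, :] + radii[None, :, None] * dirs[:, None, :])
        hu = _interp_many(self.f.hu, self.f.world_to_index(
            pts.reshape(-1, 3))).reshape(n_rays, len(radii))
        centre = float(np.mean(hu[:, 0]))
        bgs = hu.min(axis=1)
        valid = (centre - bgs) >= min_contrast_hu

        def mean_crossing(plateau):
            crossings = []
            for k in np.nonzero(valid)[0]:
                prof = hu[k]
                half = 0.5 * (plateau + bgs[k])
                below = np.nonzero(prof < half)[0]
                if len(below) == 0 or below[0] == 0:
                    continue
                i = below[0]
                t = (prof[i - 1] - half) / (prof[i - 1] - prof[i])
                crossings.append(radii[i - 1] + t * step)
            return crossings

        crossings = mean_crossing(centre)
        if len(crossings) < n_rays // 2:
            if return_offset:
                return float("nan"), np.zeros(3)
            return float("nan")
        r_c = float(np.mean(crossings))
        # lumen-centre correction from opposite-ray crossing asymmetry:
        # pins the trace to the HU tube axis, independent of the
        # vesselness ridge (which wanders under noise)
        offset = np.zeros(3)
        if return_offset:
            half_pairs = []
            percross = {}
            for k in np.nonzero(valid)[0]:
                prof = hu[k]
                halfl = 0.5 * (centre + bgs[k])
                below = np.nonzero(prof < halfl)[0]
                if len(below) and below[0] > 0:
                    i = below[0]
                    t = (prof[i - 1] - halfl) / (prof[i - 1] - prof[i])
                    percross[k] = radii[i - 1] + t * step
            n_half = n_rays // 2
            for k in range(n_half):
                if k in percross and (k + n_half) in percross:
                    half_pairs.append(
                        0.5 * (percross[k] - percross[k + n_half]) * dirs[k])
            if len(half_pairs) >= 2:
                offset = np.mean(half_pairs, axis=0)
                nrm = np.linalg.norm(offset)
                cap = 0.5 * self.min_sp
                if nrm > cap:
                    offset = offset * (cap / nrm)
        bg = float(np.median(bgs[valid]))
        # refine by the cross-section area integral, which is invariant to
        # the acquisition/raster blur that quantises the crossing estimate
        # at sub-2-voxel radii: A = integral (HU - P) / (V - P) dA
        R = 1.6 * r_c + float(self.min_sp)
        n_th = 12
        rr = np.arange(0.5 * step, R, step)
        th = np.arange(n_th) * (2 * math.pi / n_th)
        ddirs = np.outer(np.cos(th), u) + np.outer(np.sin(th), v)
        grid = p[None, None, :] + rr[None, :, None] * ddirs[:, None, :]
        g = _interp_many(self.f.hu, self.f.world_to_index(
            grid.reshape(-1, 3))).reshape(n_th, len(rr))
        ring = g[:, rr >= max(R - 2 * step, 0.7 * R)]
        P = float(np.median(ring))
        V = max(centre, P + min_contrast_hu)
        frac = np.clip((g - P) / (V - P), -0.25, 1.25)
        area = float(np.sum(frac * rr[None, :]) * step * (2 * math.pi / n_th))
        area += math.pi * (0.5 * step) ** 2      # centre cell, frac ~ 1
        r_out = r_c if area <= 0 else math.sqrt(area / math.pi)
        if return_offset:
            return r_out, offset
        return r_out

    # -- tracing ------------------------------------------------------------

    def _march(self, p0, d0, r0, path_id, max_nan_run=2, depth=0):
        """March from p0 along d0; returns (points, radii, hit path id).

        Stops on: lung exit, low response, entry into claimed territory
        (the hit id is recorded for junction fusion), death of the HU
        tube evidence (half-contrast radius fails ``max_nan_run`` steps —
        the physical tube end, robust against large filter scales
        extending the response beyond the tip), a persistent radius
        collapse (tube cap), or an unphysical turning rate.  Turning is
        measured on ~1 mm displacement baselines so that sub-voxel
        re-centring jitter does not register as curvature.  After a turn
        or low-response stop near a junction, a short straight probe is
        pushed ahead to reach the claimed territory of the crossing
        vessel, so the contact is recorded and the junction can fuse."""
        pts, radii = [], []
        p, d, r = p0.copy(), d0.copy(), r0
        nan_run = 0
        cap_run = 0
        hit_owner = None
        recent = [r0]
        k_base = max(int(round(1.0 / self.h)), 2)   # steps in ~1 mm
        probe_after = False
        probes_left = 8
        steps_since_probe = 0
        for _ in range(self.max_steps):
            steps_since_probe += 1
            q = p + self.h * d
            vox = self._voxel(q)
            if vox is None or (self.f.lung is not None and not self.f.lung[vox]):
                break
            o = self.f.orientation[vox]
            if np.linalg.norm(o) > 0:
                if np.dot(o, d) < 0:
                    o = -o
                d_new = 0.7 * o + 0.3 * d
                n = np.linalg.norm(d_new)
                d_new = d_new / n if n > 0 else d
            else:
                d_new = d
            if len(pts) >= 2 * k_base + 1 and steps_since_probe > k_base:
                v1 = np.asarray(pts[-1]) - np.asarray(pts[-1 - k_base])
                v2 = np.asarray(pts[-1 - k_base]) - np.asarray(pts[-1 - 2 * k_base])
                cosang = float(np.dot(v1, v2) /
                               max(np.linalg.norm(v1) * np.linalg.norm(v2), 1e-12))
                if cosang < math.cos(math.radians(35.0)):
                    probe_after = True
                    break
            q = self.recenter(q, d_new)
            if self.response_at(q) < self.thr:
                probe_after = True
                break
            vox = self._voxel(q)
            if vox is None:
                break
            r_new, off = self.radius_at(q, d_new, r if r > 0 else 1.0,
                                        return_offset=True)
            if not math.isnan(r_new):
                q = q + 0.5 * off
            if math.isnan(r_new):
                nan_run += 1
                if nan_run >= max_nan_run:
                    break
            else:
                nan_run = 0
                # a persistent radius collapse marks the rounded tube cap:
                # stop before the trace wraps around it
                r_run = float(np.median(recent))
                if r_new < 0.8 * r_run:
                    cap_run += 1
                    if cap_run >= 2:
                        pts.append(q)
                        radii.append(r_new)
                        break
                else:
                    cap_run = 0
                    recent.append(r_new)
                    if len(recent) > 11:
                        recent.pop(0)
                r = r_new
            owner = self.claim[vox]
            if owner >= 0 and owner != path_id:
                pts.append(q)       # keep the contact point for later fusion
                radii.append(r if math.isnan(r_new) else r_new)
                hit_owner = int(owner)
                break
            pts.append(q)
            radii.append(r_new)
            p, d = q, d_new
        # trim a trailing contrast-free tail
        while radii and math.isnan(radii[-1]):
            pts.pop()
            radii.pop()
        if probe_after and hit_owner is None and len(pts) >= 2 * k_base + 1 \
                and depth < 6:
            status, data = self._straight_probe(pts, radii, path_id, k_base)
            if status == "hit":
                hit_owner = data
            elif status == "coast":
                # the probe crossed the junction region through bright
                # lumen without meeting any claim: resume normal marching
                p_end, d_end, r_end, ppts, pradii = data
                pts.extend(ppts)
                radii.extend(pradii)
                more_pts, more_radii, more_hit = self._march(
                    p_end, d_end, r_end, path_id, max_nan_run, depth + 1)
                pts.extend(more_pts)
                radii.extend(more_radii)
                hit_owner = more_hit
        return pts, radii, hit_owner

    def _straight_probe(self, pts, radii, path_id, k_base, reach_mm=6.0):
        """Push straight ahead from a stalled trace end (frozen direction,
        no re-centring), through the low-response no-man's-land of a
        bifurcation, looking for another path's claimed territory.  The
        probe keeps going while the HU lumen stays bright; contact points
        are appended and the hit path id returned, or None at a real
        tube end (contrast death)."""
        d = np.asarray(pts[-1]) - np.asarray(pts[-1 - k_base])
        nd = np.linalg.norm(d)
        if nd == 0:
            return "end", None
        d = d / nd
        p = np.asarray(pts[-1], float)
        r = radii[-1] if not math.isnan(radii[-1]) else 1.0
        n_steps = int(reach_mm / self.h)
        probe_pts, probe_radii = [], []
        for _ in range(n_steps):
            p = p + self.h * d
            vox = self._voxel(p)
            if vox is None or (self.f.lung is not None and not self.f.lung[vox]):
                return "end", None
            r_new = self.radius_at(p, d, r)
            if math.isnan(r_new):
                return "end", None   # left the bright lumen: a real end
            r = r_new
            probe_pts.append(p.copy())
            probe_radii.append(r_new)
            owner = self.claim[vox]
            if owner >= 0 and owner != path_id:
                pts.extend(probe_pts)
                radii.extend(probe_radii)
                return "hit", int(owner)
        return "coast", (p, d, r, probe_pts, probe_radii)

    def trace_from(self, seed_idx, path_id):
        p0 = self.f.index_to_world(seed_idx)
        d0 = self.f.orientation[tuple(seed_idx)].astype(float)
        n = np.linalg.norm(d0)
        if n == 0:
            return None
        d0 /= n
        p0 = self.recenter(p0, d0)
        r_init = float(self.f.radius_mm[tuple(seed_idx)])
        r0 = self.radius_at(p0, d0, max(r_init, 0.5))
        if math.isnan(r0):
            return None
        fwd, fr, fhit = self._march(p0, d0, r0, path_id)
        bwd, br, bhit = self._march(p0, -d0, r0, path_id)
        pts = list(reversed(bwd)) + [p0] + fwd
        radii = list(reversed(br)) + [r0] + fr
        if len(pts) < 3:
            return None
        return np.asarray(pts), np.asarray(radii), (bhit, fhit)

    def claim_path(self, pts, radii, path_id):
        """Mark voxels near the path as owned, so later seeds/traces stop."""
        sp = self.f.spacing
        for p, r in zip(pts, radii):
            cr = max(self.claim_factor * r, self.min_sp)
            ctr = self.f.world_to_index(p)
            lo = np.maximum(np.floor(ctr - cr / sp).astype(int), 0)
            hi = np.minimum(np.ceil(ctr + cr / sp).astype(int) + 1, self.shape)
            if np.any(lo >= hi):
                continue
            sl = tuple(slice(a, b) for a, b in zip(lo, hi))
            grid = np.stack(np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)],
                                        indexing="ij"), axis=-1)
            world = self.f.origin + (grid + 0.5) * sp
            inside = np.sum((world - p) ** 2, axis=-1) <= cr * cr
            region = self.claim[sl]
            region[inside & (region < 0)] = path_id
            self.claim[sl] = region


def _smooth_path(pts, sigma=2.0):
    """Gaussian smoothing of the coordinates along the path; suppresses
    re-centring jitter (which would inflate arc length) while leaving the
    mm-scale generative curvature essentially untouched."""
    if len(pts) < 5:
        return pts
    out = np.empty_like(pts)
    for k in range(3):
        out[:, k] = ndimage.gaussian_filter1d(pts[:, k], sigma, mode="nearest")
    out[0], out[-1] = pts[0], pts[-1]
    return out


def _cap_trim_count(radii, pts, drop_frac=0.95, window_mm=6.0):
    """Number of points to trim from the END of a free path: the trace
    runs across the rounded tube cap (about one radius of overshoot),
    recognisable as a collapse of the measured radius below the interior
    value.  Trim length is bounded by the interior radius itself."""
    m = len(radii)
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(steps[::-1])])  # arc dist from end
    rev = np.asarray(radii, float)[::-1]
    r_ref = float(np.nanmax(rev[s <= window_mm]))
    # median-of-3 robustness against single noisy readings
    rmed = rev.copy()
    if m >= 3:
        rmed[1:-1] = np.median(np.stack([rev[:-2], rev[1:-1], rev[2:]]), axis=0)
    n = 0
    for j in range(m - 2):          # keep at least 2 points
        if s[j] > r_ref:
            break
        if rmed[j] < drop_frac * r_ref:
            n = j + 1
    if n:
        # the half-contrast radius of a hemispherical cap drops below
        # f*r only sqrt(1-f^2)*r beyond the true tube end, and the
        # partial-volume blur delays the drop by about half a voxel more
        step = 2.0 * float(np.median(steps)) if len(steps) else 0.5
        s_cut = s[n - 1] + math.sqrt(1.0 - drop_frac ** 2) * r_ref + 0.35 * step
        while n < m - 2 and s[n] <= s_cut:
            n += 1
    return n


def _fill_nan_radii(radii, max_nan_frac=0.5):
    """Interpolate unreliable (NaN) radius estimates from neighbours along
    the path; a path with mostly-NaN radii is rejected (returns None)."""
    bad = np.isnan(radii)
    if not bad.any():
        return radii
    if bad.mean() > max_nan_frac:
        return None
    idx = np.arange(len(radii))
    radii = radii.copy()
    radii[bad] = np.interp(idx[bad], idx[~bad], radii[~bad])
    return radii


def extract_paths(field: VesselnessField, seed_stride: int = 2,
                  seed_threshold: float = 0.05, trace_threshold: float = 0.01,
                  min_points: int = 3, min_length_mm: float = 4.0,
                  smooth_sigma: float = 2.0) -> list:
    """Trace sub-voxel centerline paths from regularly spaced response
    maxima, strongest seeds first.  Returns a list of
    :class:`CenterlinePath`; empty on vessel-free input."""
    if field.hu is None:
        raise ValueError("field.hu required for radius refinement")
    resp = field.response
    if not (resp > seed_threshold).any():
        return []

    # one candidate per stride-block: the block-max voxel above threshold
    fp = np.ones((2 * seed_stride + 1,) * 3, bool)
    local_max = (resp == ndimage.maximum_filter(resp, footprint=fp)) \
        & (resp > seed_threshold)
    seeds = np.argwhere(local_max)
    order = np.argsort(-resp[tuple(seeds.T)])
    seeds = seeds[order]

    step_mm = 0.5 * float(np.min(field.spacing))
    tracer = _Tracer(field, trace_threshold, step_mm)
    paths: list[CenterlinePath] = []

    for seed in seeds:
        if tracer.claim[tuple(seed)] >= 0:
            continue
        pid = len(paths)
        traced = tracer.trace_from(seed, pid)
        if traced is None or len(traced[0]) < min_points:
            continue
        pts, radii, (hit_start, hit_end) = traced
        claim_start, claim_end = hit_start is not None, hit_end is not None
        radii = _fill_nan_radii(radii)
        if radii is None:
            continue
        # free ends overshoot across the rounded tube cap; fused ends stop
        # at another path and are handled by junction snapping instead
        if not claim_end:
            n = _cap_trim_count(radii, pts)
            if n:
                pts, radii = pts[:len(pts) - n], radii[:len(radii) - n]
        if not claim_start and len(pts) >= min_points:
            n = _cap_trim_count(radii[::-1], pts[::-1])
            if n:
                pts, radii = pts[n:], radii[n:]
        if len(pts) < min_points:
            continue
        pts = _smooth_path(pts, smooth_sigma)
        arc = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        if arc < min_length_mm:
            continue
        resps = _interp_many(field.response, field.world_to_index(pts))
        path = CenterlinePath(points=pts, radii=radii, responses=resps,
                              hit_start=hit_start, hit_end=hit_end)
        tracer.claim_path(pts, radii, pid)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# segments and trees


@dataclass
class VesselSegment:
    """One vessel piece between two adjacent nodes of a tree."""

    points: np.ndarray
    radii: np.ndarray
    tree_id: int = -1
    segment_id: int = -1
    compartment: Optional[str] = None
    zone: Optional[str] = None
    arc_mm: float = 0.0
    chord_mm: float = 0.0
    distance_metric: float = 1.0
    mean_diameter_mm: float = 0.0
    volume_ml: float = 0.0
    mean_response: float = 0.0

    @classmethod
    def from_geometry(cls, points, radii, **kw):
        points = np.asarray(points, float)
        radii = np.asarray(radii, float)
        steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
        arc = float(np.sum(steps))
        chord = float(np.linalg.norm(points[-1] - points[0]))
        dm = arc / chord if chord > 1e-9 else float("nan")
        # conical-frustum quadrature for the volume
        r0, r1 = radii[:-1], radii[1:]
        vol = float(np.sum(math.pi / 3.0 * steps * (r0 ** 2 + r0 * r1 + r1 ** 2)))
        # arc-length weighted mean radius -> mean diameter
        w = np.zeros(len(points))
        w[:-1] += steps / 2.0
        w[1:] += steps / 2.0
        mean_d = 2.0 * float(np.sum(w * radii) / np.sum(w)) if arc > 0 \
            else 2.0 * float(np.mean(radii))
        return cls(points=points, radii=radii, arc_mm=arc, chord_mm=chord,
                   distance_metric=dm, mean_diameter_mm=mean_d,
                   volume_ml=vol / 1.0e3, **kw)

    @property
    def midpoint(self) -> np.ndarray:
        """Arc-length midpoint of the centerline."""
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(steps)])
        half = cum[-1] / 2.0
        i = int(np.searchsorted(cum, half))
        if i == 0:
            return self.points[0]
        t = (half - cum[i - 1]) / max(cum[i] - cum[i - 1], 1e-12)
        return self.points[i - 1] + t * (self.points[i] - self.points[i - 1])

    @property
    def orientation(self) -> np.ndarray:
        v = self.points[-1] - self.points[0]
        n = np.linalg.norm(v)
        return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


@dataclass
class VesselTree:
    tree_id: int
    graph: nx.Graph                      # nodes carry 'pos'; edges carry segment
    segments: list = field(default_factory=list)

    @property
    def n_bifurcations(self) -> int:
        return sum(1 for n in self.graph.nodes if self.graph.degree(n) >= 3)

    @property
    def total_volume_ml(self) -> float:
        return sum(s.volume_ml for s in self.segments)


def detect_junctions(field: VesselnessField, threshold: float = 0.02) -> np.ndarray:
    """Bifurcation candidates from the skeleton of the response support.

    The thresholded vesselness mask is skeletonised (topology-preserving)
    and skeleton voxels with three or more 26-neighbours are clustered
    into junction centres (world mm).  Used to split traced paths at
    branch points that endpoint fusion alone can miss."""
    from skimage.morphology import skeletonize
    mask = field.response > threshold
    if not mask.any():
        return np.zeros((0, 3))
    skel = skeletonize(mask)
    nbrs = ndimage.convolve(skel.astype(np.uint8), np.ones((3, 3, 3), np.uint8),
                            mode="constant") - skel
    bp = skel & (nbrs >= 3)
    if not bp.any():
        return np.zeros((0, 3))
    lab, n = ndimage.label(bp, structure=np.ones((3, 3, 3), bool))
    centres = ndimage.center_of_mass(bp, lab, range(1, n + 1))
    return np.array([field.index_to_world(c) for c in centres])


def _apply_junctions(paths, junctions, voxel_diag, splits, uf, snapped, attach):
    """Split paths at skeleton junction centres and bind the anchors.

    A junction is honoured when at least two distinct paths pass within
    tolerance (or one path plus another path's endpoint), which rejects
    spurious skeleton branch points caused by noise spurs."""
    from scipy.spatial import cKDTree
    per_path = [cKDTree(p.points) for p in paths]
    for j in junctions:
        cands = []
        for i, p in enumerate(paths):
            dist, idx = per_path[i].query(j)
            tol = max(voxel_diag, 1.4 * float(p.radii[int(idx)]) + 0.5)
            if dist <= tol:
                cands.append((i, int(idx)))
        # a stalled daughter whose (trimmed) endpoint stops short of the
        # junction still counts as evidence, and is bound to it
        in_cands = {i for i, _ in cands}
        end_cands = []
        for i, p in enumerate(paths):
            if i in in_cands:
                continue
            for end in (0, len(p.points) - 1):
                if np.linalg.norm(p.points[end] - j) <= 3.5:
                    end_cands.append((i, end))
                    break
        if len(cands) < 1 or len(cands) + len(end_cands) < 2:
            continue
        anchors = []
        for (i, idx) in cands:
            m = len(paths[i].points)
            if idx <= 2:
                idx = 0
            elif idx >= m - 3:
                idx = m - 1
            else:
                near = [s for s in splits[i] if abs(s - idx) <= 3]
                idx = near[0] if near else idx
                splits[i].add(idx)
            anchors.append((i, idx))
        for (i, end) in end_cands:
            # extend the stalled piece geometrically onto the junction host
            attach.setdefault((i, end), anchors[0])
        anchors.extend(end_cands)
        for a in anchors[1:]:
            uf.union(anchors[0], a)
        snapped.extend(anchors)


def _choose_attach(cands, e, d_out, lat_max, reach_fwd):
    """Pick the candidate point that continues the tip direction with the
    least lateral deviation — the attach that adds the least spurious
    kink (and hence tortuosity) to the fused geometry.

    ``cands`` is an iterable of (key, point).  Returns the best key or
    None.  A candidate must lie within ``reach_fwd`` ahead of the tip
    (small backward slack allowed) and within ``lat_max`` of the
    tangent ray."""
    best, best_score = None, np.inf
    for key, q in cands:
        v = q - e
        dist = float(np.linalg.norm(v))
        if dist < 1e-9:
            return key
        if d_out is None:
            fwd, lat = 0.0, dist
        else:
            fwd = float(np.dot(v, d_out))
            lat = math.sqrt(max(dist * dist - fwd * fwd, 0.0))
        if fwd < -0.5 or fwd > reach_fwd or lat > lat_max:
            continue
        score = lat + 0.3 * max(fwd, 0.0)
        if score < best_score:
            best, best_score = key, score
    return best


def _fusion_events(paths, voxel_diag, lumen_ok=None):
    """For each path endpoint, the point of another path to fuse with.

    An endpoint whose trace was stopped by entering another path's
    claimed territory fuses with *that* path (the contact is known);
    other endpoints fuse with a point of any other path that continues
    the tip direction within reach — the junction-gap and head-to-head
    cases.  Attach points are chosen to minimise the lateral kink."""
    from scipy.spatial import cKDTree
    all_pts, owner, pidx = [], [], []
    for i, p in enumerate(paths):
        all_pts.append(p.points)
        owner.append(np.full(len(p.points), i))
        pidx.append(np.arange(len(p.points)))
    all_pts = np.vstack(all_pts)
    owner = np.concatenate(owner)
    pidx = np.concatenate(pidx)
    tree = cKDTree(all_pts)

    events = []     # (path_a, end_idx_a, path_b, point_idx_b)
    for i, p in enumerate(paths):
        for end, hit in ((0, p.hit_start), (len(p.points) - 1, p.hit_end)):
            e = p.points[end]
            kb = min(3, len(p.points) - 1)
            d_out = e - p.points[kb if end == 0 else len(p.points) - 1 - kb]
            nd = np.linalg.norm(d_out)
            d_out = d_out / nd if nd > 0 else None
            r_end = float(p.radii[end])
            lat_max = max(voxel_diag, 2.2 * r_end)
            if hit is not None and 0 <= hit < len(paths) and hit != i:
                # contact known: restrict to the hit path, align the attach
                ph = paths[hit]
                cands = [((hit, j), ph.points[j]) for j in range(len(ph.points))
                         if np.linalg.norm(ph.points[j] - e) <= 5.0]
                key = _choose_attach(cands, e, d_out,
                                     lat_max=max(lat_max, 3.0), reach_fwd=5.0)
                if key is None and cands:
                    key = min(cands, key=lambda c: np.linalg.norm(c[1] - e))[0]
                if key is not None:
                    events.append((i, end, key[0], int(key[1])))
                continue
            cands = [((int(owner[k]), int(pidx[k])), all_pts[k])
                     for k in tree.query_ball_point(e, max(lat_max, 4.0))
                     if owner[k] != i]
            if lumen_ok is not None:
                cands = [(key, q) for key, q in cands
                         if np.linalg.norm(q - e) <= voxel_diag
                         or lumen_ok(e, q)]
            key = _choose_attach(cands, e, d_out, lat_max=lat_max,
                                 reach_fwd=4.0)
            if key is not None:
                events.append((i, end, key[0], int(key[1])))
    return events


class _UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def build_trees(paths, spacing, fuse_tol_mm: Optional[float] = None,
                junctions: Optional[np.ndarray] = None,
                field: Optional[VesselnessField] = None) -> list:
    """Fuse traced paths into trees and split them at bifurcations.

    Junction identity is established by the fusion events themselves
    (union-find over path anchors), not by positional tolerance, so
    mutually attaching endpoints always share one node.  Returns a list
    of :class:`VesselTree`; each edge of a tree graph is one
    :class:`VesselSegment` with recomputed arc/chord/DM/volume.  Cycles
    created by spurious fusions are broken by dropping the
    weakest-response closing edge (logged).
    """
    if not paths:
        return []
    spacing = np.asarray(spacing, float)
    voxel_diag = float(np.linalg.norm(spacing))

    lumen_ok = None
    if field is not None and field.hu is not None:
        def lumen_ok(a, b, _f=field):
            # a fusion bridge must stay inside bright lumen; crossing
            # parenchyma means the two structures are separate vessels
            t = np.linspace(0.0, 1.0, 7)[1:-1][:, None]
            pts = a[None, :] + t * (b - a)[None, :]
            hu = _interp_many(_f.hu, _f.world_to_index(pts))
            return bool(hu.min() > -550.0)

    events = _fusion_events(paths, voxel_diag, lumen_ok)
    # anchors per path: endpoints plus interior split indices
    splits = {i: set() for i in range(len(paths))}
    attach = {}      # (path, end_index) -> (other path, point index)
    uf = _UnionFind()
    snapped_events = []
    for (ia, end, ib, kb) in events:
        pb = paths[ib]
        # snap near-endpoint hits onto the endpoint; snap interior hits
        # onto a nearby existing split so twin daughters share a node
        if kb <= 2:
            kb = 0
        elif kb >= len(pb.points) - 3:
            kb = len(pb.points) - 1
        else:
            near = [s for s in splits[ib] if abs(s - kb) <= 3]
            kb = near[0] if near else kb
            splits[ib].add(kb)
        attach[(ia, end)] = (ib, kb)
        snapped_events.append((ia, end, ib, kb))
    for (ia, end, ib, kb) in snapped_events:
        uf.union((ia, end), (ib, kb))

    if junctions is not None and len(junctions):
        extra = []
        _apply_junctions(paths, junctions, voxel_diag, splits, uf, extra, attach)

    def node_of(ip, k):
        return uf.find((ip, k))

    G = nx.MultiGraph()
    node_pos = {}
    for i, p in enumerate(paths):
        cut = sorted({0, len(p.points) - 1} | splits[i])
        for a, b in zip(cut[:-1], cut[1:]):
            if b - a < 1:
                continue
            pts = p.points[a:b + 1].copy()
            radii = p.radii[a:b + 1].copy()
            resp = p.responses[a:b + 1]
            # extend terminal pieces to their junction on the other path
            for pos in (a, b):
                key = (i, pos)
                if pos in (0, len(p.points) - 1) and key in attach:
                    ib, kb = attach[key]
                    jp = paths[ib].points[kb]
                    jr = paths[ib].radii[kb]
                    if pos == a and np.linalg.norm(pts[0] - jp) > 1e-9:
                        pts = np.vstack([jp, pts])
                        radii = np.concatenate([[jr], radii])
                    elif pos == b and np.linalg.norm(pts[-1] - jp) > 1e-9:
                        pts = np.vstack([pts, jp])
                        radii = np.concatenate([radii, [jr]])
            na, nb = node_of(i, a), node_of(i, b)
            if na == nb and b - a < 5:
                continue        # degenerate micro-loop
            arc = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
            G.add_edge(na, nb, points=pts, radii=radii,
                       mean_response=float(np.mean(resp)),
                       weight=arc * (0.1 + float(np.mean(resp))))
            node_pos.setdefault(na, pts[0])
            node_pos.setdefault(nb, pts[-1])
    for n in G.nodes:
        G.nodes[n]["pos"] = node_pos[n]

    _close_terminal_gaps(G, voxel_diag, lumen_ok)

    # break cycles: keep a maximum spanning forest weighted by edge arc
    # times response, so spurious short/weak closing connections (bridges,
    # junction jumps) are the ones dropped, never a real branch
    for u, v, k, data in G.edges(keys=True, data=True):
        if "weight" not in data:
            arc = float(np.sum(np.linalg.norm(np.diff(data["points"], axis=0),
                                              axis=1)))
            data["weight"] = arc * (0.1 + float(data["mean_response"]))
    keep = set()
    for comp in nx.connected_components(G):
        sg = G.subgraph(comp)
        for u, v, k, _ in nx.maximum_spanning_edges(
                sg, weight="weight", keys=True, data=True):
            keep.add((u, v, k))
            keep.add((v, u, k))
    drop = [(u, v, k) for u, v, k in G.edges(keys=True)
            if (u, v, k) not in keep]
    if drop:
        logger.info("breaking %d cycle edge(s) by lowest response", len(drop))
        G.remove_edges_from(drop)

    _contract_degree2(G)
    _prune_spurs(G)
    _contract_degree2(G)
    _split_kinks(G, baseline_mm=1.2, angle_deg=20.0)
    _split_junction_signatures(G)
    _prune_spurs(G)
    _straighten_junction_zones(G)

    trees = []
    for t, comp in enumerate(nx.connected_components(G)):
        sg = nx.Graph()
        segs = []
        for u, v, data in G.subgraph(comp).edges(data=True):
            seg = VesselSegment.from_geometry(
                data["points"], data["radii"], tree_id=t,
                segment_id=len(segs), mean_response=data["mean_response"])
            segs.append(seg)
            sg.add_edge(u, v, segment=seg)
        for n in comp:
            sg.nodes[n]["pos"] = G.nodes[n]["pos"]
        if segs:
            trees.append(VesselTree(tree_id=t, graph=sg, segments=segs))
    return trees


def _close_terminal_gaps(G: nx.MultiGraph, voxel_diag, lumen_ok=None,
                         reach_mm=5.0):
    """Connect loose tips to nearby vessel geometry on the built graph.

    Traces stop somewhat unpredictably inside the low-response region of
    a bifurcation, so a tip can be left a few millimetres short of the
    vessel it belongs to.  For every degree-1 node, search other edges'
    polylines within ``reach_mm``: a point roughly ahead of the tip (or
    within the radial tolerance) is accepted, the host edge is split
    there, and a short straight bridge edge is added."""
    from scipy.spatial import cKDTree

    edge_list = list(G.edges(keys=True, data=True))
    if not edge_list:
        return
    pts_all, ref = [], []
    for eidx, (u, v, k, data) in enumerate(edge_list):
        pts_all.append(data["points"])
        ref.extend((eidx, j) for j in range(len(data["points"])))
    pts_all = np.vstack(pts_all)
    tree = cKDTree(pts_all)

    split_requests = {}     # eidx -> list of (point_idx, tip_node)
    for n in [n for n in G.nodes if G.degree(n) == 1]:
        u, v, k, data = next(iter(G.edges(n, keys=True, data=True)))
        pts = data["points"]
        at_start = bool(np.allclose(G.nodes[n]["pos"], pts[0]))
        tip = pts[0] if at_start else pts[-1]
        inner = pts[min(4, len(pts) - 1)] if at_start \
            else pts[max(len(pts) - 5, 0)]
        d_out = tip - inner
        nd = np.linalg.norm(d_out)
        if nd == 0:
            continue
        d_out /= nd
        r_tip = float(data["radii"][0 if at_start else -1])
        own_edge = next(eidx for eidx, (eu, ev, ek, _) in enumerate(edge_list)
                        if ek == k and {eu, ev} == {u, v})
        cands = [(ref[j], pts_all[j])
                 for j in tree.query_ball_point(tip, reach_mm)
                 if ref[j][0] != own_edge]
        if lumen_ok is not None:
            cands = [(key, q) for key, q in cands
                     if np.linalg.norm(q - tip) <= voxel_diag
                     or lumen_ok(tip, q)]
        best = _choose_attach(cands, tip, d_out,
                              lat_max=max(voxel_diag, 2.2 * r_tip),
                              reach_fwd=reach_mm)
        if best is not None:
            split_requests.setdefault(best[0], []).append((best[1], n))

    for eidx, req in split_requests.items():
        u, v, k, data = edge_list[eidx]
        if not G.has_edge(u, v, k):
            continue
        pts, radii = data["points"], data["radii"]
        mresp = data["mean_response"]
        req = sorted(req)
        cuts = sorted({pj for pj, _ in req if 2 <= pj <= len(pts) - 3})
        # carve the host edge at the requested interior points
        bounds = [0] + cuts + [len(pts) - 1]
        G.remove_edge(u, v, k)
        seg_nodes = [u] + [f"gap{eidx}_{c}" for c in cuts] + [v]
        for a, b, na, nb in zip(bounds[:-1], bounds[1:],
                                seg_nodes[:-1], seg_nodes[1:]):
            if b - a < 1:
                continue
            G.add_edge(na, nb, points=pts[a:b + 1].copy(),
                       radii=radii[a:b + 1].copy(), mean_response=mresp)
            G.nodes[na]["pos"] = pts[a]
            G.nodes[nb]["pos"] = pts[b]
        for pj, tip_node in req:
            if pj < 2:
                host = u
            elif pj > len(pts) - 3:
                host = v
            else:
                host = f"gap{eidx}_{min(cuts, key=lambda c: abs(c - pj))}"
            if host == tip_node or G.has_edge(host, tip_node):
                continue
            tp = np.asarray(G.nodes[tip_node]["pos"], float)
            hp = np.asarray(G.nodes[host]["pos"], float)
            if np.linalg.norm(tp - hp) < 1e-9:
                continue
            bridge_pts = np.vstack([tp, hp])
            tip_edges = list(G.edges(tip_node, keys=True, data=True))
            rr = float(tip_edges[0][3]["radii"][0]) if tip_edges else 1.0
            G.add_edge(tip_node, host, points=bridge_pts,
                       radii=np.array([rr, rr]),
                       mean_response=0.0)


def _straighten_junction_zones(G: nx.MultiGraph, zone_radii=2.0):
    """Replace edge geometry near junction/split nodes by straight runs
    and lightly smooth each assembled edge.

    Inside the merged lumen of a junction the ridge between branches is
    ill-defined and the trace weaves, inflating arc length; the
    centreline within ~2 local radii of a branch point carries no
    meaningful tortuosity information, so it is linearised."""
    deg3 = {n for n in G.nodes if G.degree(n) >= 2}
    for (u, v, k, data) in G.edges(keys=True, data=True):
        pts, radii = data["points"], data["radii"]
        if len(pts) < 4:
            continue
        arc_total = float(np.sum(np.linalg.norm(np.diff(pts, axis=0),
                                                axis=1)))
        for node, at_start in ((u, True), (v, False)):
            if node not in deg3:
                continue
            npos = np.asarray(G.nodes[node]["pos"], float)
            rr = float(radii[0] if at_start else radii[-1])
            zone = zone_radii * max(rr, 1.0)
            d2 = np.linalg.norm(pts - npos[None, :], axis=1)
            inside = d2 <= zone
            if at_start:
                j = int(np.argmax(~inside)) if (~inside).any() else len(pts) - 1
                if j > 1:
                    t = np.linspace(0, 1, j + 1)[:, None]
                    pts[:j + 1] = pts[0] + t * (pts[j] - pts[0])
            else:
                rev = inside[::-1]
                j = int(np.argmax(~rev)) if (~rev).any() else len(pts) - 1
                if j > 1:
                    a = len(pts) - 1 - j
                    t = np.linspace(0, 1, len(pts) - a)[:, None]
                    pts[a:] = pts[a] + t * (pts[-1] - pts[a])
        data["points"] = _smooth_path(pts, 1.5)


def _split_kinks(G: nx.MultiGraph, baseline_mm=1.2, angle_deg=20.0,
                 min_piece_mm=3.0):
    """Split edges at interior curvature spikes.

    A trace that coasts through a bifurcation whose third branch never
    connected carries a localized kink at the junction; vessels
    themselves bend smoothly (a few degrees per mm).  Splitting at the
    kink restores the two anatomical segments, as segments are defined
    between branch points."""
    for (u, v, k, data) in list(G.edges(keys=True, data=True)):
        pts, radii = data["points"], data["radii"]
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(steps)])
        if cum[-1] < 2 * min_piece_mm:
            continue
        kb = max(int(round(baseline_mm / max(np.median(steps), 1e-9))), 2)
        if len(pts) < 2 * kb + 1:
            continue
        v1 = pts[2 * kb:] - pts[kb:-kb]
        v2 = pts[kb:-kb] - pts[:-2 * kb]
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        cosang = np.einsum("ij,ij->i", v1, v2) / np.maximum(n1 * n2, 1e-12)
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        # local maxima above threshold, away from the ends
        cuts = []
        for j in range(1, len(ang) - 1):
            idx = j + kb
            if ang[j] >= angle_deg and ang[j] >= ang[j - 1] \
                    and ang[j] >= ang[j + 1] \
                    and min_piece_mm <= cum[idx] <= cum[-1] - min_piece_mm:
                if not cuts or cum[idx] - cum[cuts[-1]] > 2 * min_piece_mm:
                    cuts.append(idx)
        if not cuts:
            continue
        G.remove_edge(u, v, k)
        bounds = [0] + cuts + [len(pts) - 1]
        names = [u] + [f"kink_{id(data)}_{c}" for c in cuts] + [v]
        for a, b, na, nb in zip(bounds[:-1], bounds[1:], names[:-1], names[1:]):
            G.add_edge(na, nb, points=pts[a:b + 1].copy(),
                       radii=radii[a:b + 1].copy(),
                       mean_response=data["mean_response"])
            G.nodes[na]["pos"] = pts[a]
            G.nodes[nb]["pos"] = pts[b]


def _split_junction_signatures(G: nx.MultiGraph, baseline_mm=3.0,
                               angle_deg=12.0, bump_ratio=1.12,
                               min_piece_mm=4.0):
    """Split edges where an unresolved branch point was crossed.

    A trace coasting through a bifurcation shows two co-located
    signatures: the direction turns by at least the branching angle
    (spread over the junction-sized region, hence the ~3 mm baseline)
    and the measured radius bumps up where the ray fan sees both
    branches.  Requiring both keeps genuinely tortuous but smooth-walled
    segments intact."""
    for (u, v, k, data) in list(G.edges(keys=True, data=True)):
        pts, radii = data["points"], data["radii"]
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(steps)])
        if cum[-1] < 2 * min_piece_mm or len(pts) < 12:
            continue
        step = max(float(np.median(steps)), 1e-9)
        kb = max(int(round(baseline_mm / step)), 3)
        kw = max(int(round(1.5 / step)), 2)      # bump window ~1.5 mm
        km = max(int(round(6.0 / step)), 5)      # reference window ~6 mm
        if len(pts) < 2 * kb + 1:
            continue
        v1 = pts[2 * kb:] - pts[kb:-kb]
        v2 = pts[kb:-kb] - pts[:-2 * kb]
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        cosang = np.einsum("ij,ij->i", v1, v2) / np.maximum(n1 * n2, 1e-12)
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        cuts = []
        for j in range(1, len(ang) - 1):
            idx = j + kb
            if ang[j] < angle_deg or ang[j] < ang[j - 1] or ang[j] < ang[j + 1]:
                continue
            if not (min_piece_mm <= cum[idx] <= cum[-1] - min_piece_mm):
                continue
            lo, hi = max(0, idx - km), min(len(radii), idx + km + 1)
            ref = float(np.median(radii[lo:hi]))
            bump = float(np.max(radii[max(0, idx - kw):idx + kw + 1]))
            if ref <= 0 or bump / ref < bump_ratio:
                continue
            if not cuts or cum[idx] - cum[cuts[-1]] > 2 * min_piece_mm:
                cuts.append(idx)
        if not cuts:
            continue
        G.remove_edge(u, v, k)
        bounds = [0] + cuts + [len(pts) - 1]
        names = [u] + [f"jsig_{id(data)}_{c}" for c in cuts] + [v]
        for a, b, na, nb in zip(bounds[:-1], bounds[1:], names[:-1],
                                names[1:]):
            G.add_edge(na, nb, points=pts[a:b + 1].copy(),
                       radii=radii[a:b + 1].copy(),
                       mean_response=data["mean_response"])
            G.nodes[na]["pos"] = pts[a]
            G.nodes[nb]["pos"] = pts[b]


def _prune_spurs(G: nx.MultiGraph, radius_factor=2.0, cap_mm=4.5):
    """Remove dangling stubs at junctions.

    A leaf edge much shorter than the local vessel calibre, hanging off
    a bifurcation node, is a tracing artefact of the junction blob, not
    an anatomical branch (real daughters are centimetres long)."""
    changed = True
    while changed:
        changed = False
        for (u, v, k, data) in list(G.edges(keys=True, data=True)):
            du, dv = G.degree(u), G.degree(v)
            if 1 not in (du, dv) or max(du, dv) < 3:
                continue
            chord = float(np.linalg.norm(data["points"][-1]
                                         - data["points"][0]))
            r_mean = float(np.mean(data["radii"]))
            if chord < min(radius_factor * r_mean, cap_mm):
                leaf = u if du == 1 else v
                G.remove_edge(u, v, k)
                if G.degree(leaf) == 0:
                    G.remove_node(leaf)
                changed = True


def _absorb_short_pieces(G: nx.MultiGraph, radius_factor=2.0, cap_mm=4.5):
    """Merge junction-zone slivers back into their neighbours.

    Splitting can leave a piece much shorter than the local calibre
    between a junction node and a split node; such a piece is junction
    interior, not a segment.  It is merged with the edge on its
    degree-2 side."""
    changed = True
    while changed:
        changed = False
        for (u, v, k, data) in list(G.edges(keys=True, data=True)):
            if not G.has_edge(u, v, k):
                continue
            chord = float(np.linalg.norm(data["points"][-1]
                                         - data["points"][0]))
            r_mean = float(np.mean(data["radii"]))
            if chord >= min(radius_factor * r_mean, cap_mm):
                continue
            for n in (u, v):
                if G.degree(n) == 2 and u != v and \
                        _collinear_at(G, n, max_angle_deg=30.0):
                    _contract_node(G, n)
                    changed = True
                    break
            if changed:
                break


def _collinear_at(G, n, max_angle_deg=30.0):
    """True when the two edges at a degree-2 node continue each other's
    direction (merging them adds no kink)."""
    edges = list(G.edges(n, keys=True, data=True))
    if len(edges) != 2:
        return False
    pos = np.asarray(G.nodes[n]["pos"], float)
    dirs = []
    for (eu, ev, ek, ed) in edges:
        pts = ed["points"]
        if np.linalg.norm(pts[0] - pos) < np.linalg.norm(pts[-1] - pos):
            a, b = pts[0], pts[min(len(pts) - 1, 4)]
        else:
            a, b = pts[-1], pts[max(0, len(pts) - 5)]
        d = b - a
        nn = np.linalg.norm(d)
        if nn == 0:
            return False
        dirs.append(d / nn)
    cosang = -float(np.dot(dirs[0], dirs[1]))   # outgoing vs incoming
    return cosang > math.cos(math.radians(max_angle_deg))


def _contract_node(G: nx.MultiGraph, n):
    """Merge the two edges meeting at a degree-2 node into one."""
    edges = list(G.edges(n, keys=True, data=True))
    if len(edges) != 2:
        return
    (u1, v1, k1, d1), (u2, v2, k2, d2) = edges
    o1 = v1 if u1 == n else u1
    o2 = v2 if u2 == n else u2
    if o1 == n or o2 == n:
        return
    pos = np.asarray(G.nodes[n]["pos"], float)
    p1, r1 = d1["points"], d1["radii"]
    if np.linalg.norm(p1[-1] - pos) > np.linalg.norm(p1[0] - pos):
        p1, r1 = p1[::-1], r1[::-1]
    p2, r2 = d2["points"], d2["radii"]
    if np.linalg.norm(p2[0] - pos) > np.linalg.norm(p2[-1] - pos):
        p2, r2 = p2[::-1], r2[::-1]
    join = np.allclose(p1[-1], p2[0])
    pts = np.vstack([p1, p2[1:]]) if join else np.vstack([p1, p2])
    radii = np.concatenate([r1, r2[1:]]) if join else np.concatenate([r1, r2])
    mresp = 0.5 * (d1["mean_response"] + d2["mean_response"])
    G.remove_edge(u1, v1, k1)
    G.remove_edge(u2, v2, k2)
    G.remove_node(n)
    G.add_edge(o1, o2, points=pts, radii=radii, mean_response=mresp)


def _contract_degree2(G: nx.MultiGraph):
    """Merge the two edges at every degree-2 node (trace fragmentation),
    preserving geometry order."""
    changed = True
    while changed:
        changed = False
        for n in list(G.nodes):
            if G.degree(n) != 2:
                continue
            edges = list(G.edges(n, keys=True, data=True))
            if len(edges) != 2:
                continue
            (u1, v1, k1, d1), (u2, v2, k2, d2) = edges
            o1 = v1 if u1 == n else u1
            o2 = v2 if u2 == n else u2
            if o1 == n or o2 == n:      # self loop, leave alone
                continue
            p1, r1 = d1["points"], d1["radii"]
            if np.linalg.norm(p1[-1] - G.nodes[n]["pos"]) > \
                    np.linalg.norm(p1[0] - G.nodes[n]["pos"]):
                p1, r1 = p1[::-1], r1[::-1]
            p2, r2 = d2["points"], d2["radii"]
            if np.linalg.norm(p2[0] - G.nodes[n]["pos"]) > \
                    np.linalg.norm(p2[-1] - G.nodes[n]["pos"]):
                p2, r2 = p2[::-1], r2[::-1]
            pts = np.vstack([p1, p2[1:]]) if np.allclose(p1[-1], p2[0]) \
                else np.vstack([p1, p2])
            radii = np.concatenate([r1, r2[1:]]) if np.allclose(p1[-1], p2[0]) \
                else np.concatenate([r1, r2])
            mresp = 0.5 * (d1["mean_response"] + d2["mean_response"])
            G.remove_edge(u1, v1, k1)
            G.remove_edge(u2, v2, k2)
            G.remove_node(n)
            G.add_edge(o1, o2, points=pts, radii=radii, mean_response=mresp)
            changed = True
            break


def filter_by_diameter(segments, min_mm: float = MIN_DIAMETER_MM,
                       max_mm: float = MAX_DIAMETER_MM) -> list:
    """Keep segments with min_mm <= mean diameter <= max_mm (inclusive)."""
    if min_mm >= max_mm:
        raise ValueError("min diameter must be below max diameter")
    kept = []
    for s in segments:
        if min_mm <= s.mean_diameter_mm <= max_mm:
            kept.append(s)
        else:
            logger.debug("dropping segment %s/%s: mean diameter %.2f mm "
                         "outside [%g, %g]", s.tree_id, s.segment_id,
                         s.mean_diameter_mm, min_mm, max_mm)
    return kept


def canonical_axis_order(values, spacing):
    """A permutation of axes derived from grid shape, spacing and a 1-D
    content signature, identical for any axis-permuted copy of the same
    scene.  Running extraction in this canonical order makes world-space
    outputs exactly invariant to how the input grid was laid out."""
    shape = values.shape
    keys = []
    for ax in range(3):
        others = tuple(i for i in range(3) if i != ax)
        prof = np.asarray(values, np.float64).sum(axis=others)
        sig = tuple(np.round(prof[:: max(len(prof) // 32, 1)], 1))
        keys.append((-shape[ax], float(spacing[ax]), sig))
    return tuple(sorted(range(3), key=lambda ax: keys[ax]))


def segments_to_mask(segments, like) -> LabelMask:
    """Paint the extracted segments as tubes into a binary mask aligned
    with ``like`` (a CtVolume or LabelMask)."""
    from scipy.spatial import cKDTree
    shape = like.shape
    spacing = np.asarray(like.spacing, float)
    origin = np.asarray(like.origin, float)
    out = np.zeros(shape, np.uint8)
    for s in segments:
        pts, radii = s.points, s.radii
        rmax = float(np.max(radii))
        lo = np.maximum(np.floor((pts.min(axis=0) - rmax - spacing - origin)
                                 / spacing - 0.5).astype(int), 0)
        hi = np.minimum(np.ceil((pts.max(axis=0) + rmax + spacing - origin)
                                / spacing - 0.5).astype(int) + 1,
                        np.asarray(shape))
        if np.any(lo >= hi):
            continue
        ii = [np.arange(lo[k], hi[k]) for k in range(3)]
        gx, gy, gz = np.meshgrid(*ii, indexing="ij")
        centres = origin + (np.stack([gx, gy, gz], axis=-1) + 0.5) * spacing
        tree = cKDTree(pts)
        d, k = tree.query(centres.reshape(-1, 3),
                          distance_upper_bound=rmax + 1e-6)
        k = np.minimum(k, len(pts) - 1)
        inside = (d <= np.asarray(radii)[k]).reshape(gx.shape)
        sub = out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[inside] = 1
        out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sub
    return LabelMask(out, spacing, origin)


def extract_vessels(vol: CtVolume, lung: LabelMask,
                    scales_mm=DEFAULT_SCALES_MM,
                    min_diameter_mm: float = MIN_DIAMETER_MM,
                    max_diameter_mm: float = MAX_DIAMETER_MM,
                    intensity: Optional[CtVolume] = None,
                    boundary_erosion_mm: float = 2.0,
                    **trace_kw):
    """Convenience wrapper: vesselness -> paths -> trees -> diameter filter.

    The computation runs in a canonical axis order (see
    :func:`canonical_axis_order`) so results do not depend on how the
    input grid happens to be laid out; outputs are mapped back to the
    caller's axes.  Returns ``(trees, segments)`` where ``segments`` is
    the flat, diameter-filtered list used by morphometry.
    """
    perm = canonical_axis_order(vol.values, vol.spacing)
    inv = tuple(np.argsort(perm))
    if perm != (0, 1, 2):
        vol = CtVolume(np.ascontiguousarray(np.transpose(vol.values, perm)),
                       spacing=np.asarray(vol.spacing)[list(perm)],
                       origin=np.asarray(vol.origin)[list(perm)])
        lung = LabelMask(np.ascontiguousarray(
            np.transpose(lung.values, perm)), vol.spacing, vol.origin)
        if intensity is not None:
            intensity = CtVolume(np.ascontiguousarray(
                np.transpose(intensity.values, perm)), vol.spacing,
                vol.origin)
    field = compute_vesselness(vol, lung, scales_mm,
                               boundary_erosion_mm=boundary_erosion_mm,
                               intensity=intensity)
    paths = extract_paths(field, **trace_kw)
    junctions = detect_junctions(field)
    trees = build_trees(paths, vol.spacing, junctions=junctions, field=field)
    segments = filter_by_diameter(
        [s for t in trees for s in t.segments], min_diameter_mm, max_diameter_mm)
    if perm != (0, 1, 2):
        for t in trees:
            for s in t.segments:
                s.points = s.points[:, list(inv)]
            for n in t.graph.nodes:
                t.graph.nodes[n]["pos"] = np.asarray(
                    t.graph.nodes[n]["pos"])[list(inv)]
    return trees, segments
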