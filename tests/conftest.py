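import math

import numpy as np
import pytest

from vesselquant import (PhantomSpec, PhantomTruth, SegmentTruth,
                         generate_phantom, rasterize)


def straight_tube_truth(radius=2.0, half_len=30.0, axes=(40, 10, 10)):
    pts = np.stack([np.linspace(-half_len, half_len, 121),
                    np.zeros(121), np.zeros(121)], axis=1)
    seg = SegmentTruth(points=pts, radius_mm=radius, tree_id=0,
                       compartment="vein", arc_mm=2 * half_len,
                       chord_mm=2 * half_len, distance_metric=1.0)
    return PhantomTruth(segments=[seg], airways=[], lung_axes=axes,
                        lung_centre=np.zeros(3), lung_volume_l=0.02)


def y_truth(r_parent=2.2, r_child=1.8, angle_deg=35.0):
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

    a = math.radians(angle_deg)
    parent = seg(line([-25, 0, 0], [0, 0, 0]), r_parent)
    d1 = seg(line([0, 0, 0], [20 * math.cos(a), 20 * math.sin(a), 0]), r_child)
    d2 = seg(line([0, 0, 0], [20 * math.cos(a), -20 * math.sin(a), 0]),
             r_child)
    return PhantomTruth(segments=[parent, d1, d2], airways=[],
                        lung_axes=(34, 20, 10), lung_centre=np.zeros(3),
                        lung_volume_l=0.03)


def render(truth, spacing=0.7, noise=20.0, seed=0, **spec_kw):
    spec = PhantomSpec(lung_axes=truth.lung_axes, spacing=(spacing,) * 3,
                       noise_sd=noise, seed=seed,
                       vessel_volume_fraction=None, **spec_kw)
    return rasterize(truth, spec)


@pytest.fixture(scope="session")
def tube_scene():
    """Straight 4 mm tube rendered at 0.5 mm with noise."""
    truth = straight_tube_truth()
    vol, masks = render(truth, spacing=0.5, seed=0)
    return truth, vol, masks


@pytest.fixture(scope="session")
def y_scene():
    truth = y_truth()
    vol, masks = render(truth, spacing=0.7, seed=0)
    return truth, vol, masks


@pytest.fixture(scope="session")
def recovery_phantom():
    """One default-condition phantom with full ground truth (computed
    once per session; several tests read different aspects of it)."""
    spec = PhantomSpec(seed=1)
    truth = generate_phantom(spec)
    vol, masks = rasterize(truth, spec)
    return spec, truth, vol, masks
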