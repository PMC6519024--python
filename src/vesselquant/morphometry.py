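"""Per-subject morphological readouts.

Whole-lung and zonal metrics over the diameter-filtered segment set:

* normalized vessel volume — cumulative segment volume as % of the
  (total or zonal) lung volume;
* vessel density — segment count per litre of lung;
* tortuosity — median per-segment distance metric (DM = arc/chord);
* heterogeneity — width between the 15th and 85th DM percentiles;
* mean lung attenuation — mean HU of lung parenchyma after removing
  vessel and airway voxels.

Zones are thirds of equal lung volume along the cranio-caudal axis;
segments belong to the zone containing their arc-length midpoint (ties
go caudal).  Percentiles use linear interpolation between order
statistics throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .image_io import CtVolume, LabelMask

ZONES = ("lower", "middle", "upper")
REGIONS = ("whole",) + ZONES
COMPARTMENTS = ("all", "artery", "vein")


def normalized_volume(segments, region_volume_l: float) -> float:
    """100 x (sum of segment volumes) / region volume."""
    if region_volume_l <= 0:
        raise ValueError("region volume must be positive")
    total_ml = sum(s.volume_ml for s in segments)
    return 100.0 * total_ml / (region_volume_l * 1.0e3)


def vessel_density(segments, region_volume_l: float) -> float:
    """Segment count per litre of region volume."""
    if region_volume_l <= 0:
        raise ValueError("region volume must be positive")
    return len(segments) / region_volume_l


def tortuosity_and_heterogeneity(segments):
    """(median DM, P85 - P15 of DM); NaN markers when undefined."""
    dm = np.asarray([s.distance_metric for s in segments], float)
    dm = dm[np.isfinite(dm)]
    if len(dm) == 0:
        return float("nan"), float("nan")
    med = float(np.median(dm))
    if len(dm) < 2:
        return med, float("nan")
    p15, p85 = np.percentile(dm, [15, 85])  # linear interpolation
    return med, float(p85 - p15)


def mean_lung_attenuation(vol: CtVolume, lung: LabelMask,
                          airway: Optional[LabelMask] = None,
                          vessel: Optional[LabelMask] = None) -> float:
    """Mean HU over lung voxels excluding airway and vessel voxels."""
    sel = lung.values > 0
    if airway is not None:
        sel &= ~(airway.values > 0)
    if vessel is not None:
        sel &= ~(vessel.values > 0)
    if not sel.any():
        raise ValueError("no parenchymal voxels left after exclusions")
    return float(vol.values[sel].mean())


def zonal_split(lung: LabelMask):
    """Split the lung into three equal-volume cranio-caudal zones.

    Returns (zone masks dict, cut z-world positions (z1, z2)).  Cut
    planes sit where the cumulative caudal-to-cranial lung volume crosses
    1/3 and 2/3; increasing z index is caudal -> cranial, so the lower
    zone occupies the smallest z indices.
    """
    counts = (lung.values > 0).sum(axis=(0, 1)).astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty lung mask")
    nz = np.nonzero(counts)[0]
    if len(nz) < 3:
        raise ValueError("lung thinner than 3 slices cannot be zoned")
    cum = np.cumsum(counts)
    k1 = int(np.searchsorted(cum, total / 3.0))
    k2 = int(np.searchsorted(cum, 2.0 * total / 3.0))
    k2 = max(k2, k1 + 1)

    masks = {}
    for name, (a, b) in zip(ZONES, [(0, k1 + 1), (k1 + 1, k2 + 1),
                                    (k2 + 1, lung.shape[2])]):
        m = np.zeros_like(lung.values)
        m[:, :, a:b] = lung.values[:, :, a:b]
        masks[name] = LabelMask(m, lung.spacing, lung.origin)
    # world z of the upper faces of the boundary slabs
    z1 = lung.index_to_world([0, 0, k1 + 0.5])[2]
    z2 = lung.index_to_world([0, 0, k2 + 0.5])[2]
    return masks, (float(z1), float(z2))


def assign_zones(segments, cuts) -> None:
    """Set ``segment.zone`` from the arc-length midpoint z (ties caudal)."""
    z1, z2 = cuts
    for s in segments:
        z = float(s.midpoint[2])
        if z <= z1:
            s.zone = "lower"
        elif z <= z2:
            s.zone = "middle"
        else:
            s.zone = "upper"


@dataclass
class SubjectMetrics:
    """The full compartment x region metric grid for one subject."""

    total_lung_volume_l: float
    zone_volumes_l: dict
    mean_lung_attenuation_hu: dict          # region -> HU
    metrics: dict = dc_field(default_factory=dict)
    # metrics[(compartment, region)] = {"normalized_volume_pct": ...,
    #   "density_per_l": ..., "tortuosity": ..., "heterogeneity": ...,
    #   "n_segments": ...}

    def get(self, compartment, region, name):
        entry = self.metrics.get((compartment, region))
        return None if entry is None else entry.get(name)

    def to_dict(self) -> dict:
        out = {
            "total_lung_volume_l": self.total_lung_volume_l,
            "zone_volumes_l": dict(self.zone_volumes_l),
            "mean_lung_attenuation_hu": dict(self.mean_lung_attenuation_hu),
            "metrics": {},
        }
        for (c, r), vals in self.metrics.items():
            out["metrics"][f"{c}/{r}"] = vals
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)

    @property
    def flat(self) -> dict:
        """Flat column dict for cohort tables (whole-lung, all + AV)."""
        cols = {
            "total_lung_volume_l": self.total_lung_volume_l,
            "mean_lung_attenuation_hu":
                self.mean_lung_attenuation_hu.get("whole"),
        }
        names = {"normalized_volume_pct": "normalized_%s_volume_pct",
                 "density_per_l": "%s_density_per_l",
                 "tortuosity": "%s_tortuosity",
                 "heterogeneity": "%s_heterogeneity"}
        for c in COMPARTMENTS:
            e = self.metrics.get((c, "whole"))
            if e is None:
                continue
            tag = "vessel" if c == "all" else c
            for key, fmt in names.items():
                cols[fmt % tag] = e[key]
        return cols


def compute_subject_metrics(vol: CtVolume, lung: LabelMask, segments,
                            airway: Optional[LabelMask] = None,
                            vessel_mask: Optional[LabelMask] = None,
                            av_labelled: bool = True) -> SubjectMetrics:
    """Fill the compartment x region metric grid for one subject.

    Artery/vein entries are produced only when ``av_labelled`` and at
    least one segment carries a compartment label; undefined quantities
    are NaN, never silent zeros.
    """
    zone_masks, cuts = zonal_split(lung)
    assign_zones(segments, cuts)
    tlv = lung.volume_l()
    zone_vol = {z: zone_masks[z].volume_l() for z in ZONES}

    mla = {"whole": mean_lung_attenuation(vol, lung, airway, vessel_mask)}
    for z in ZONES:
        mla[z] = mean_lung_attenuation(vol, zone_masks[z], airway, vessel_mask)

    have_av = av_labelled and any(
        s.compartment in ("artery", "vein") for s in segments)

    m = SubjectMetrics(total_lung_volume_l=tlv, zone_volumes_l=zone_vol,
                       mean_lung_attenuation_hu=mla)
    compartments = COMPARTMENTS if have_av else ("all",)
    for c in compartments:
        if c == "all":
            csegs = segments
        else:
            csegs = [s for s in segments if s.compartment == c]
        for r in REGIONS:
            rsegs = csegs if r == "whole" else [s for s in csegs if s.zone == r]
            rvol = tlv if r == "whole" else zone_vol[r]
            tort, het = tortuosity_and_heterogeneity(rsegs)
            m.metrics[(c, r)] = {
                "normalized_volume_pct": normalized_volume(rsegs, rvol),
                "density_per_l": vessel_density(rsegs, rvol),
                "tortuosity": tort,
                "heterogeneity": het,
                "n_segments": len(rsegs),
            }
    return m
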