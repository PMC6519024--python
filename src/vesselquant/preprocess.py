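"""CT pre-filtering plus lung and airway masks.

External (clinical-grade) masks are the preferred inputs and pass through
untouched; the threshold/region-growing fallbacks below exist so phantoms
run end-to-end without any external segmenter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import CtVolume, LabelMask

LUNG_THRESHOLD_HU = -400.0
AIRWAY_THRESHOLD_HU = -950.0


@dataclass
class PrepResult:
    filtered: CtVolume
    lung: LabelMask
    airway: LabelMask          # may be empty
    total_lung_volume_l: float


def median_prefilter(vol: CtVolume) -> CtVolume:
    """1-voxel-wide (3x3x3) median filter with nearest-edge replication."""
    out = ndimage.median_filter(vol.values, size=3, mode="nearest")
    return CtVolume(values=out, spacing=vol.spacing, origin=vol.origin)


def segment_lung(vol: CtVolume, closing_radius_mm: float = 3.5) -> LabelMask:
    """Threshold-based lung mask: low-attenuation voxels not connected to
    the image border, largest components kept, morphologically closed so
    vessels are re-included in the lung volume."""
    air = vol.values < LUNG_THRESHOLD_HU
    # remove border-connected air (outside the body envelope)
    lab, n = ndimage.label(air)
    if n == 0:
        raise ValueError(
            f"empty lung mask: no voxels below {LUNG_THRESHOLD_HU} HU")
    border_labels = set(np.unique(np.concatenate([
        lab[0].ravel(), lab[-1].ravel(), lab[:, 0].ravel(),
        lab[:, -1].ravel(), lab[:, :, 0].ravel(), lab[:, :, -1].ravel()])))
    border_labels.discard(0)
    counts = np.bincount(lab.ravel())
    keep = [i for i in range(1, n + 1)
            if i not in border_labels and counts[i] > 100]
    if not keep:
        raise ValueError(
            f"empty lung mask: no interior component below "
            f"{LUNG_THRESHOLD_HU} HU")
    # keep components within 20% of the largest (two lungs), drop debris
    cmax = max(counts[i] for i in keep)
    keep = [i for i in keep if counts[i] >= 0.2 * cmax]
    lung = np.isin(lab, keep)

    r_vox = max(int(round(closing_radius_mm / float(min(vol.spacing)))), 1)
    struct = _ball(r_vox)
    lung = ndimage.binary_closing(lung, structure=struct)
    lung = ndimage.binary_fill_holes(lung)
    return LabelMask(lung.astype(np.uint8), vol.spacing, vol.origin)


def _ball(r: int) -> np.ndarray:
    z = np.arange(-r, r + 1)
    x, y, zz = np.meshgrid(z, z, z, indexing="ij")
    return (x * x + y * y + zz * zz) <= r * r


def segment_airways(vol: CtVolume, seed_point, max_hu: float = AIRWAY_THRESHOLD_HU,
                    step_hu: float = 10.0) -> LabelMask:
    """26-connected region growth from a seed inside an air-filled lumen.

    Growth proceeds in HU-threshold increments up to ``max_hu``; a step
    that more than doubles the grown volume is treated as a leak into the
    parenchyma and rolled back.
    """
    seed_idx = tuple(int(round(i)) for i in np.asarray(seed_point))
    if any(i < 0 or i >= s for i, s in zip(seed_idx, vol.shape)):
        raise ValueError(f"seed voxel {seed_idx} outside the volume")
    seed_hu = float(vol.values[seed_idx])
    if seed_hu >= max_hu:
        raise ValueError(
            f"seed voxel at {seed_hu:.0f} HU is not air "
            f"(requires < {max_hu:.0f} HU)")

    struct = np.ones((3, 3, 3), bool)
    thresholds = np.arange(min(seed_hu + step_hu, max_hu), max_hu + 1e-6, step_hu)
    prev = None
    for thr in thresholds:
        cand = vol.values < thr
        lab, _ = ndimage.label(cand, structure=struct)
        region = lab == lab[seed_idx]
        if prev is not None and region.sum() > 2 * prev.sum():
            region = prev  # leak: roll back to the previous threshold
            break
        prev = region
    if prev is None or not prev.any():
        raise ValueError("airway region growth produced an empty region")
    return LabelMask(prev.astype(np.uint8), vol.spacing, vol.origin)


def prepare(vol: CtVolume, lung_mask: LabelMask | None = None,
            airway_mask: LabelMask | None = None,
            airway_seed=None, prefilter: bool = True) -> PrepResult:
    """Run the pre-processing stage: median filter, then lung/airway masks
    (external masks take precedence over the built-in fallbacks).

    Total lung volume is taken from the lung mask *before* any vessel
    removal, i.e. it includes vessel voxels; normalized vessel volume is
    therefore a fraction of a volume that contains the vessels.
    """
    filtered = median_prefilter(vol) if prefilter else vol
    if lung_mask is None:
        lung_mask = segment_lung(filtered)
    if airway_mask is None:
        if airway_seed is not None:
            airway_mask = segment_airways(filtered, airway_seed)
        else:
            airway_mask = LabelMask(np.zeros(vol.shape, np.uint8),
                                    vol.spacing, vol.origin)
            warnings.warn("no airway mask or seed given; airway mask empty, "
                          "artery/vein labelling will be unavailable")
    tlv = lung_mask.volume_l()
    if tlv <= 0:
        raise ValueError("total lung volume must be positive")
    return PrepResult(filtered=filtered, lung=lung_mask, airway=airway_mask,
                      total_lung_volume_l=tlv)
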