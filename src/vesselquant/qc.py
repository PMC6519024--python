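"""Extraction-quality control and cohort assembly.

Two fractions grade each subject's vessel extraction against a reference
(truth or annotation) mask:

* ``frac_spurious`` — proportion of extracted vessel volume that is not
  vascular in the reference;
* ``frac_missed`` — proportion of reference vessel volume the extraction
  missed.

A subject is excluded from all analyses when either fraction exceeds
10% (strict), and additionally from artery/vein analyses when the AV
mislabelling fraction exceeds 20% (strict).  Fractions are
volume-weighted by default (count-weighting available via masks of
labelled structures is out of scope here).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

EXTRACTION_THRESHOLD = 0.10
AV_THRESHOLD = 0.20


@dataclass
class QcReport:
    frac_spurious: float
    frac_missed: float
    frac_av_mislabelled: Optional[float] = None
    motion_flag: bool = False

    @property
    def excluded_extraction(self) -> bool:
        return bool(self.frac_spurious > EXTRACTION_THRESHOLD
                    or self.frac_missed > EXTRACTION_THRESHOLD
                    or self.motion_flag)

    @property
    def excluded_av(self) -> bool:
        if self.excluded_extraction:
            return True
        f = self.frac_av_mislabelled
        return bool(f is not None and np.isfinite(f) and f > AV_THRESHOLD)

    def to_json(self, path) -> None:
        d = asdict(self)
        d["excluded_extraction"] = self.excluded_extraction
        d["excluded_av"] = self.excluded_av
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, default=float)


def qc_against_truth(extracted_mask, truth_mask,
                     frac_av_mislabelled: Optional[float] = None,
                     motion_flag: bool = False) -> QcReport:
    """Compute the two QC fractions from aligned binary masks."""
    ev = np.asarray(extracted_mask.values if hasattr(extracted_mask, "values")
                    else extracted_mask) > 0
    tv = np.asarray(truth_mask.values if hasattr(truth_mask, "values")
                    else truth_mask) > 0
    if ev.shape != tv.shape:
        raise ValueError(f"mask grids differ: {ev.shape} vs {tv.shape}")
    n_ex = float(ev.sum())
    n_tr = float(tv.sum())
    spurious = float((ev & ~tv).sum()) / n_ex if n_ex > 0 else 0.0
    missed = float((tv & ~ev).sum()) / n_tr if n_tr > 0 else 0.0
    return QcReport(frac_spurious=spurious, frac_missed=missed,
                    frac_av_mislabelled=frac_av_mislabelled,
                    motion_flag=motion_flag)


AV_COLUMNS_PREFIXES = ("artery_", "vein_", "normalized_artery_",
                       "normalized_vein_")


def assemble_cohort(metric_rows, qc_reports, clinical: Optional[pd.DataFrame]
                    = None) -> pd.DataFrame:
    """Join per-subject metrics, QC flags and clinical data.

    ``metric_rows``: dict subject_id -> flat metric dict;
    ``qc_reports``: dict subject_id -> QcReport.  Extraction-excluded
    subjects are dropped entirely; AV-excluded subjects keep their row
    but have artery/vein columns set to missing.
    """
    ids = list(metric_rows.keys())
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate subject ids")
    rows = []
    n_excluded = 0
    n_av_excluded = 0
    for sid in ids:
        qc = qc_reports.get(sid)
        if qc is not None and qc.excluded_extraction:
            n_excluded += 1
            continue
        row = {"subject_id": sid}
        row.update(metric_rows[sid])
        if qc is not None:
            row["frac_spurious"] = qc.frac_spurious
            row["frac_missed"] = qc.frac_missed
            row["frac_av_mislabelled"] = qc.frac_av_mislabelled
            if qc.excluded_av:
                n_av_excluded += 1
                for col in list(row):
                    if col.startswith(AV_COLUMNS_PREFIXES):
                        row[col] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    if clinical is not None:
        if "subject_id" not in clinical.columns:
            raise ValueError("clinical table lacks a subject_id column")
        if clinical["subject_id"].duplicated().any():
            raise ValueError("duplicate subject ids in clinical table")
        out = out.merge(clinical, on="subject_id", how="left")
    out.attrs["n_extraction_excluded"] = n_excluded
    out.attrs["n_av_excluded"] = n_av_excluded
    return out
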