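"""Structure-function statistics: linear regressions and group tests.

Univariable and covariate-adjusted multivariable ordinary least squares
of pulmonary-function variables on quantitative CT metrics, with 95%
t-based confidence intervals and two-sided p-values; group differences
via Student's t, chi-square, or Mann-Whitney U per variable type.
Complete-case analysis per model, no multiple-testing correction by
default (a Holm option exists behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

#: metric pairs above this pairwise R^2 are flagged as collinear and
#: should not enter a joint model
COLLINEARITY_R2 = 0.5

#: the four standard adjusters of the multivariable models
DEFAULT_ADJUSTERS = ("age_years", "male", "smoking_ever",
                     "slice_thickness_mm")


@dataclass
class RegressionResult:
    dependent: str
    term: str
    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    r_squared: float
    n: int
    kind: str = "univariable"

    def __post_init__(self):
        if not self.ci_low <= self.beta <= self.ci_high:
            raise ValueError("confidence interval must contain the estimate")


@dataclass
class GroupComparison:
    variable: str
    test: str                   # "t" | "chi-square" | "mann-whitney"
    statistic: float
    p_value: float


def _design(cohort: pd.DataFrame, dependent: str, terms: Sequence[str]):
    cols = [dependent] + list(terms)
    df = cohort[cols].dropna()
    if len(df) < len(terms) + 2:
        raise ValueError(
            f"too few complete cases ({len(df)}) for model on {dependent}")
    X = df[list(terms)].astype(float)
    for c in X.columns:
        if X[c].nunique() <= 1:
            raise ValueError(f"constant model column: {c}")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design; near-duplicate columns "
                         f"{worst[0]} and {worst[1]}")
    return df, Xc


def _fit(cohort, dependent, terms, kind):
    df, Xc = _design(cohort, dependent, terms)
    model = sm.OLS(df[dependent].astype(float), Xc).fit()
    ci = model.conf_int(alpha=0.05)
    out = []
    for term in terms:
        out.append(RegressionResult(
            dependent=dependent, term=term,
            beta=float(model.params[term]),
            ci_low=float(ci.loc[term, 0]), ci_high=float(ci.loc[term, 1]),
            p_value=float(model.pvalues[term]),
            r_squared=float(model.rsquared), n=int(model.nobs), kind=kind))
    return out


def univariable(cohort: pd.DataFrame, dependent: str,
                term: str) -> RegressionResult:
    """OLS of ``dependent`` on a single term plus intercept."""
    return _fit(cohort, dependent, [term], "univariable")[0]


def multivariable(cohort: pd.DataFrame, dependent: str,
                  terms: Sequence[str],
                  adjusters: Sequence[str] = DEFAULT_ADJUSTERS) -> list:
    """Covariate-adjusted OLS; returns results for the terms of interest
    (adjuster coefficients are fitted but not reported)."""
    all_terms = list(terms) + [a for a in adjusters if a not in terms]
    res = _fit(cohort, dependent, all_terms, "multivariable")
    return [r for r in res if r.term in terms]


def collinearity_guard(cohort: pd.DataFrame, term_pairs,
                       threshold: float = COLLINEARITY_R2) -> pd.DataFrame:
    """Pairwise R^2 between metric columns; pairs above threshold are
    flagged for exclusion from joint models."""
    rows = []
    for a, b in term_pairs:
        df = cohort[[a, b]].dropna()
        r = float(df[a].corr(df[b])) if len(df) > 2 else np.nan
        r2 = r * r if np.isfinite(r) else np.nan
        rows.append({"term_a": a, "term_b": b, "r_squared": r2,
                     "flagged": bool(np.isfinite(r2) and r2 > threshold)})
    return pd.DataFrame(rows)


def compare_groups(cohort: pd.DataFrame, group_flag: str,
                   continuous: Sequence[str] = (),
                   categorical: Sequence[str] = (),
                   nonnormal: Sequence[str] = ()) -> list:
    """Group differences: Student's t (continuous), chi-square
    (categorical), Mann-Whitney U (explicitly flagged non-normal)."""
    g = cohort[group_flag].astype(bool)
    a, b = cohort[g], cohort[~g]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    out = []
    for col in continuous:
        x, y = a[col].dropna(), b[col].dropna()
        t, p = sps.ttest_ind(x, y, equal_var=True)
        out.append(GroupComparison(col, "t", float(t), float(p)))
    for col in categorical:
        tab = pd.crosstab(cohort[group_flag], cohort[col])
        chi2, p, _, _ = sps.chi2_contingency(tab)
        out.append(GroupComparison(col, "chi-square", float(chi2), float(p)))
    for col in nonnormal:
        x, y = a[col].dropna(), b[col].dropna()
        u, p = sps.mannwhitneyu(x, y, alternative="two-sided")
        out.append(GroupComparison(col, "mann-whitney", float(u), float(p)))
    return out


def holm_correction(results: Sequence[RegressionResult]) -> dict:
    """Optional Holm step-down adjustment of regression p-values."""
    ps = [(i, r.p_value) for i, r in enumerate(results)]
    ps.sort(key=lambda t: t[1])
    m = len(ps)
    adj = {}
    running = 0.0
    for rank, (i, p) in enumerate(ps):
        running = max(running, (m - rank) * p)
        adj[i] = min(running, 1.0)
    return {results[i].term: adj[i] for i in adj}


def results_frame(results: Sequence[RegressionResult]) -> pd.DataFrame:
    rows = [{
        "dependent": r.dependent, "ct_pattern": r.term, "n": r.n,
        "beta": r.beta, "ci_low": r.ci_low, "ci_high": r.ci_high,
        "p_value": r.p_value, "r_squared": r.r_squared, "model": r.kind,
    } for r in results]
    return pd.DataFrame(rows)


def render_tables(results: Sequence[RegressionResult], out_dir) -> dict:
    """Write regression results as CSV and aligned text tables, grouped
    by model kind (one section per dependent variable)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = results_frame(results)
    written = {}
    for kind in (["univariable", "multivariable"] if len(frame) else []):
        sub = frame[frame.model == kind].drop(columns="model")
        csv_path = out_dir / f"{kind}.csv"
        txt_path = out_dir / f"{kind}.txt"
        sub.to_csv(csv_path, index=False, float_format="%.6g")
        with open(txt_path, "w") as fh:
            if len(sub):
                for dep, grp in sub.groupby("dependent", sort=False):
                    fh.write(f"== {dep} ==\n")
                    fh.write(grp.drop(columns="dependent")
                             .to_string(index=False,
                                        float_format=lambda v: f"{v:.3g}"))
                    fh.write("\n\n")
            else:
                fh.write("\t".join(sub.columns) + "\n")
        written[kind] = csv_path
    if not len(frame):
        csv_path = out_dir / "univariable.csv"
        pd.DataFrame(columns=["dependent", "ct_pattern", "n", "beta",
                              "ci_low", "ci_high", "p_value", "r_squared"]
                     ).to_csv(csv_path, index=False)
        written["univariable"] = csv_path
    return written
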