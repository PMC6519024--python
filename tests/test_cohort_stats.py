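import numpy as np
import pandas as pd
import pytest

from vesselquant import (CohortSpec, collinearity_guard, compare_groups,
                         generate_cohort, multivariable, univariable)
from vesselquant.cohort_stats import render_tables, results_frame


class TestUnivariable:
    def test_exact_line_recovered(self):
        x = np.arange(20, dtype=float)
        df = pd.DataFrame({"x": x, "y": 3.0 * x + 5.0})
        r = univariable(df, "y", "x")
        assert r.beta == pytest.approx(3.0, abs=1e-12)
        assert r.r_squared == pytest.approx(1.0, abs=1e-12)
        assert r.ci_high - r.ci_low == pytest.approx(0.0, abs=1e-9)

    def test_matches_closed_form_normal_equations(self):
        # fixed 5-point input; hand solvable normal equations
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 2.5, 3.9, 4.1, 5.6])
        df = pd.DataFrame({"x": x, "y": y})
        r = univariable(df, "y", "x")
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        beta = sxy / sxx
        assert r.beta == pytest.approx(beta, abs=1e-9)
        resid = y - (y.mean() - beta * x.mean()) - beta * x
        r2 = 1 - np.sum(resid ** 2) / np.sum((y - y.mean()) ** 2)
        assert r.r_squared == pytest.approx(r2, abs=1e-9)

    def test_independent_columns_near_zero_r2(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.normal(size=10_000),
                           "y": rng.normal(size=10_000)})
        assert univariable(df, "y", "x").r_squared < 0.01

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)})
        with pytest.raises(ValueError, match="constant"):
            univariable(df, "y", "x")

    def test_population_r2_recovered_at_cohort_scale(self):
        """Cohorts generated with population R^2 0.45 between normalized
        vessel volume and TLC recover it at n = 131."""
        fitted = []
        for seed in range(8):
            df = generate_cohort(CohortSpec(n_subjects=131, seed=seed))
            r = univariable(df, "tlc_pct_pred",
                            "normalized_vessel_volume_pct")
            fitted.append(r.r_squared)
        assert np.mean(fitted) == pytest.approx(0.45, abs=0.05)
        assert all(abs(f - 0.45) < 0.15 for f in fitted)


class TestMultivariable:
    def _cohort(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "vol": rng.normal(3.6, 0.8, n),
            "het": rng.normal(0.058, 0.006, n),
            "age_years": rng.integers(40, 85, n).astype(float),
            "male": rng.integers(0, 2, n).astype(float),
            "smoking_ever": rng.integers(0, 2, n).astype(float),
            "slice_thickness_mm": rng.choice([0.7, 1.0], n),
        })
        df["dlco"] = (40.0 - 5.0 * (df.vol - 3.6) - 600.0 * (df.het - 0.058)
                      + rng.normal(0, 4.0, n))
        return df

    def test_orthogonal_adjusters_leave_beta_unchanged(self):
        df = self._cohort()
        uni = univariable(df, "dlco", "vol")
        multi = multivariable(df, "dlco", ["vol"],
                              adjusters=["age_years", "male"])
        # adjusters are independent of vol by construction
        assert multi[0].beta == pytest.approx(uni.beta, abs=0.1)

    def test_duplicate_column_rank_error(self):
        df = self._cohort()
        df["vol2"] = df["vol"]
        with pytest.raises(ValueError, match="rank"):
            multivariable(df, "dlco", ["vol", "vol2"], adjusters=[])

    def test_power_at_generator_effect_sizes(self):
        """Both volume and heterogeneity terms reach significance in the
        vast majority of replicates at realistic effect sizes."""
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            df = self._cohort(n=131, seed=seed)
            res = multivariable(df, "dlco", ["vol", "het"])
            if all(r.p_value < 0.05 for r in res):
                hits += 1
        assert hits / n_rep >= 0.90


class TestCollinearity:
    def test_identical_columns_flagged(self):
        df = pd.DataFrame({"a": np.arange(50.0)})
        df["b"] = df["a"]
        out = collinearity_guard(df, [("a", "b")])
        assert out.flagged.item()
        assert out.r_squared.item() == pytest.approx(1.0)

    def test_independent_columns_not_flagged(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.normal(size=10_000),
                           "b": rng.normal(size=10_000)})
        assert not collinearity_guard(df, [("a", "b")]).flagged.item()

    def test_generator_couples_volume_and_density(self):
        df = generate_cohort(CohortSpec(n_subjects=2000, seed=3))
        out = collinearity_guard(df, [("normalized_vessel_volume_pct",
                                       "vessel_density_per_l")])
        assert out.flagged.item()


class TestGroupComparisons:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 1, 60)
        df = pd.DataFrame({"v": np.concatenate([base, base]),
                           "g": [0] * 60 + [1] * 60})
        out = compare_groups(df, "g", continuous=["v"])
        assert out[0].p_value > 0.9

    def test_three_sd_shift_detected(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "v": np.concatenate([rng.normal(0, 1, 50),
                                 rng.normal(3, 1, 50)]),
            "g": [0] * 50 + [1] * 50})
        out = compare_groups(df, "g", continuous=["v"],
                             nonnormal=["v"])
        assert all(o.p_value < 0.001 for o in out)

    def test_categorical_split_detected(self):
        df = pd.DataFrame({
            "c": ["x"] * 90 + ["y"] * 10 + ["x"] * 10 + ["y"] * 90,
            "g": [0] * 100 + [1] * 100})
        out = compare_groups(df, "g", categorical=["c"])
        assert out[0].test == "chi-square"
        assert out[0].p_value < 0.001

    def test_single_group_rejected(self):
        df = pd.DataFrame({"v": [1.0, 2.0], "g": [1, 1]})
        with pytest.raises(ValueError):
            compare_groups(df, "g", continuous=["v"])


class TestRenderTables:
    def test_empty_results_header_only(self, tmp_path):
        written = render_tables([], tmp_path)
        frame = pd.read_csv(written["univariable"])
        assert len(frame) == 0 and "beta" in frame.columns

    def test_mixed_results_grouped(self, tmp_path):
        df = pd.DataFrame({"x": np.arange(30.0),
                           "z": np.arange(30.0) ** 1.5})
        df["y"] = 2 * df.x + np.sin(df.x)
        res = [univariable(df, "y", "x"),
               *multivariable(df, "y", ["x"], adjusters=["z"])]
        written = render_tables(res, tmp_path)
        uni = pd.read_csv(written["univariable"])
        multi = pd.read_csv(written["multivariable"])
        assert len(uni) == 1 and len(multi) == 1
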