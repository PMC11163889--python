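"""Stratification, LOESS, ICC, Welch t, trend regression, percent change."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from discmorph.stats import (age_group_of, icc_two_way, loess_fit,
                             percent_change, stratify, trend_fit, welch_t)

# Shrout & Fleiss's classic 6-target x 4-judge reliability matrix
SF_MATRIX = np.array([[9, 2, 5, 8], [6, 1, 3, 2], [8, 4, 6, 8],
                      [7, 1, 2, 6], [10, 5, 6, 9], [6, 2, 4, 7]], dtype=float)


class TestStratify:
    def test_level_and_age_groups(self):
        df = pd.DataFrame({"scan_id": ["s"] * 4, "level_index": [6, 2, 10, 15],
                           "age_years": [9.0, 3.0, 4.0, 10.5], "sex": ["F"] * 4})
        out = stratify(df)
        assert list(out["level_group"]) == ["mid_thoracic", "upper_thoracic",
                                            "low_thoracic", "lumbar"]
        assert list(out["age_group"]) == ["juvenile", "infantile", "juvenile",
                                          "juvenile"]

    def test_age_group_boundaries(self):
        assert age_group_of(3.0) == "infantile"
        assert age_group_of(3.9) == "infantile"   # floor(3.9) = 3
        assert age_group_of(4.0) == "juvenile"
        assert age_group_of(10.5) == "juvenile"
        assert age_group_of(11.0) == "adolescent"
        with pytest.raises(ValueError):
            age_group_of(18.5)

    def test_merge_from_manifest_series(self):
        df = pd.DataFrame({"scan_id": ["a", "b"], "level_index": [1, 14]})
        ages = pd.Series({"a": 2.0, "b": 15.0})
        sexes = pd.Series({"a": "M", "b": "F"})
        out = stratify(df, ages=ages, sexes=sexes)
        assert list(out["age_group"]) == ["infantile", "adolescent"]
        assert list(out["sex"]) == ["M", "F"]


class TestLoess:
    def test_exact_on_lines(self, rng):
        x = np.sort(rng.uniform(0, 18, 60))
        y = 2 * x + 1
        for span in (0.3, 0.6, 1.0):
            fit = loess_fit(x, y, span=span, query=np.linspace(1, 17, 9))
            assert np.allclose(fit.fitted, 2 * fit.query + 1, atol=1e-9)

    def test_span_one_equals_ols(self, rng):
        x = rng.uniform(0, 10, 40)
        y = 3 * x - 2 + rng.normal(0, 1, 40)
        slope, intercept, *_ = sps.linregress(x, y)
        fit = loess_fit(x, y, span=1.0, degree=1, query=np.array([0.0, 5.0, 10.0]))
        assert np.allclose(fit.fitted, slope * fit.query + intercept, atol=1e-8)

    def test_local_fit_beats_global_line_on_parabola(self, rng):
        x = np.linspace(-2, 2, 80)
        y = x ** 2
        interior = np.linspace(-1, 1, 11)
        fit = loess_fit(x, y, span=0.3, query=interior)
        slope, intercept, *_ = sps.linregress(x, y)
        err_loess = np.max(np.abs(fit.fitted - interior ** 2))
        err_ols = np.max(np.abs(slope * interior + intercept - interior ** 2))
        assert err_loess < err_ols

    def test_quadratic_degree_two_exact(self, rng):
        x = np.sort(rng.uniform(0, 5, 50))
        y = 1.5 * x ** 2 - x + 4
        fit = loess_fit(x, y, span=0.5, degree=2, query=x[5:-5])
        assert np.allclose(fit.fitted, 1.5 * fit.query ** 2 - fit.query + 4,
                           atol=1e-8)

    def test_shift_equivariance_in_x(self, rng):
        x = np.sort(rng.uniform(0, 10, 50))
        y = np.sin(x) + rng.normal(0, 0.05, 50)
        q = np.linspace(2, 8, 7)
        f0 = loess_fit(x, y, span=0.4, query=q).fitted
        f1 = loess_fit(x + 100.0, y, span=0.4, query=q + 100.0).fitted
        assert np.allclose(f0, f1, atol=1e-8)

    def test_agrees_with_statsmodels_lowess(self, rng):
        """Independent cross-check: degree-1 tricube smoother from
        statsmodels on the same span, evaluated at the data points."""
        import statsmodels.api as sm
        x = np.sort(rng.uniform(0, 10, 120))
        y = np.sin(x) + rng.normal(0, 0.1, 120)
        ours = loess_fit(x, y, span=0.4, query=x).fitted
        ref = sm.nonparametric.lowess(y, x, frac=0.4, it=0, return_sorted=False)
        # different neighbour/tie conventions at the boundaries: compare RMS
        assert np.sqrt(np.mean((ours - ref) ** 2)) < 0.05

    def test_input_validation(self):
        with pytest.raises(ValueError, match="span"):
            loess_fit([1, 2, 3, 4], [1, 2, 3, 4], span=0.0)
        with pytest.raises(ValueError, match="degree\\+2"):
            loess_fit([1, 2], [1, 2], degree=1)


class TestICC:
    def test_identical_raters_give_one(self):
        X = np.tile(np.arange(10.0)[:, None], (1, 3))
        res = icc_two_way(X)
        assert res.icc == pytest.approx(1.0)
        assert res.ci95 == (pytest.approx(1.0), pytest.approx(1.0))

    def test_independent_noise_near_zero(self, rng):
        X = rng.normal(size=(1000, 2))
        assert abs(icc_two_way(X).icc) < 0.05

    def test_matches_hand_anova_oracle(self):
        """Mean-squares oracle computed from first principles on the
        Shrout & Fleiss matrix."""
        X = SF_MATRIX
        n, k = X.shape
        grand = X.mean()
        msr = k * ((X.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((X.mean(0) - grand) ** 2).sum() / (k - 1)
        sse = ((X - X.mean(1)[:, None] - X.mean(0)[None, :] + grand) ** 2).sum()
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        res = icc_two_way(X)
        assert res.icc == pytest.approx(expected, abs=1e-12)
        assert res.icc == pytest.approx(0.29, abs=0.005)  # published value

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        n, k = SF_MATRIX.shape
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "score": SF_MATRIX.ravel()})
        ref = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                       ratings="score")
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        row = ref[ref["Type"].str.contains("A,1|ICC2")].iloc[0]
        res = icc_two_way(SF_MATRIX)
        assert res.icc == pytest.approx(row["ICC"], abs=1e-6)
        assert res.ci95[0] == pytest.approx(row[ci_col][0], abs=0.01)
        assert res.ci95[1] == pytest.approx(row[ci_col][1], abs=0.01)

    def test_shift_invariance(self, rng):
        X = rng.normal(5, 1, size=(30, 3)) + rng.normal(0, 2, 30)[:, None]
        a = icc_two_way(X)
        b = icc_two_way(X + 123.4)
        assert a.icc == pytest.approx(b.icc, abs=1e-10)

    def test_error_cases(self):
        with pytest.raises(ValueError, match="at least 2"):
            icc_two_way(np.ones((5, 1)))
        with pytest.raises(ValueError, match="undefined"):
            icc_two_way(np.full((4, 3), 7.0))


class TestWelch:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        t, df, p = welch_t(a, a)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 2, 25)
        t1, df1, p1 = welch_t(a, b)
        t2, df2, p2 = welch_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert df1 == pytest.approx(df2)
        assert p1 == pytest.approx(p2)

    def test_power_at_printed_group_separation(self, rng):
        """Groups like the mid-thoracic slenderness means (0.23 vs 0.27,
        sd 0.02, n=40 each) must be detected at p < 0.001 nearly always."""
        hits = 0
        for _ in range(100):
            a = rng.normal(0.23, 0.02, 40)
            b = rng.normal(0.27, 0.02, 40)
            if welch_t(a, b)[2] < 0.001:
                hits += 1
        assert hits >= 95

    def test_small_sample_errors(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestTrendAndPercentChange:
    def _table(self, rng, n=200, slope=0.0):
        age = rng.uniform(0, 18, n)
        return pd.DataFrame({"age_years": age,
                             "sex": rng.choice(["M", "F"], n),
                             "y": slope * age + rng.normal(0, 1, n)})

    def test_linear_outcome_recovered(self, rng):
        df = pd.DataFrame({"age_years": np.arange(20.0) * 0.9,
                           "sex": ["M"] * 20, "y": 3.0 * np.arange(20.0) * 0.9 + 1})
        res = trend_fit(df, "y")
        assert res.slope == pytest.approx(3.0, abs=1e-9)
        assert res.p_value < 1e-12

    def test_null_p_values_uniform(self, rng):
        ps = [trend_fit(self._table(rng, n=60), "y").p_value for _ in range(300)]
        stat, p = sps.kstest(ps, "uniform")
        assert p > 0.01

    def test_constant_shift_changes_intercept_only(self, rng):
        df = self._table(rng, slope=0.5)
        a = trend_fit(df, "y")
        df2 = df.assign(y=df["y"] + 10)
        b = trend_fit(df2, "y")
        assert a.slope == pytest.approx(b.slope)
        assert b.intercept - a.intercept == pytest.approx(10.0)

    def test_sex_adjustment_reports_coefficient(self, rng):
        df = self._table(rng, slope=0.2)
        df["y"] += np.where(df["sex"] == "M", 1.0, 0.0)
        res = trend_fit(df, "y", adjust_for_sex=True)
        assert res.sex_coef == pytest.approx(1.0, abs=0.5)

    def test_constant_age_errors(self):
        df = pd.DataFrame({"age_years": [5.0] * 10, "sex": ["M"] * 10,
                           "y": np.arange(10.0)})
        with pytest.raises(ValueError):
            trend_fit(df, "y")

    def test_percent_change_conventions(self, rng):
        x = np.linspace(0, 18, 50)
        fit = loess_fit(x, np.full(50, 7.0), span=0.5, query=x)
        assert percent_change(fit) == pytest.approx(100.0)
        fit = loess_fit(x, 100.0 + 20.0 * x, span=1.0, query=x)
        assert percent_change(fit) == pytest.approx(460.0, rel=1e-6)
        # growth "from 4 to 7 mm" is 175% under this convention
        fit = loess_fit(x, 4.0 + (3.0 / 18.0) * x, span=1.0, query=x)
        assert percent_change(fit) == pytest.approx(175.0, rel=1e-6)

    def test_percent_change_recovers_generative_growth_factor(self, table, rng):
        """Per-subject lumbar male CSA sampled from the default growth
        curves (x5.2 birth-to-18) recovers ~520% through LOESS, provided
        the span resolves the steep infancy phase."""
        curves = table.curves("lumbar", "M")
        ages = rng.uniform(0, 18, 300)
        csa = np.array([curves.at(a)["csa_mm2"] for a in ages])
        csa *= rng.lognormal(0, 0.01, ages.size)
        # span 0.2 keeps the boundary windows inside the (linear) infancy
        # and adolescent phases, where local-linear LOESS is unbiased
        fit = loess_fit(ages, csa, span=0.2, query=np.array([0.0, 18.0]))
        assert percent_change(fit) == pytest.approx(520.0, abs=5.0)

    def test_percent_change_nonpositive_start_errors(self, rng):
        x = np.linspace(0, 18, 30)
        fit = loess_fit(x, x - 9.0, span=1.0, query=x)
        with pytest.raises(ValueError):
            percent_change(fit)
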