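"""Statistical layer: change scores, correlations, OLS, paired t, FDR, mediation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from somnostat.simulate import CohortSimConfig, generate_cohort
from somnostat.stats import (
    bh_fdr,
    correlate,
    log_transform,
    mediation_bootstrap,
    ols_regression,
    overnight_change,
    paired_t,
)


class TestOvernightChange:
    def test_no_change(self):
        assert overnight_change(30, 30, 30) == 0.0

    def test_sign_convention(self):
        # morning 35 after evenings 40/38: anxiety fell by 4
        assert overnight_change(40, 38, 35) == -4.0

    def test_two_evening_measures_averaged(self):
        assert overnight_change(40, 30, 36) == pytest.approx(36 - 35)

    def test_missing_propagates_nan(self):
        out = overnight_change([40, np.nan], [38, 38], [35, 35])
        assert np.isnan(out[1]) and out[0] == -4.0


class TestCorrelate:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = correlate(x, x)
        assert res.r == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        res = correlate([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.r == pytest.approx(0.6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            correlate([1, 2, 3, 4], [5, 5, 5, 5])

    def test_spearman_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = x**3 + rng.normal(size=30) * 0.1  # monotone-ish, no ties
        rs = correlate(x, y, method="spearman")
        rp = correlate(
            pd.Series(x).rank().to_numpy(), pd.Series(y).rank().to_numpy(), "pearson"
        )
        assert rs.r == pytest.approx(rp.r, abs=1e-12)

    def test_fisher_ci_contains_r(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        res = correlate(x, y)
        assert res.ci_low < res.r < res.ci_high


class TestOLS:
    def test_perfect_fit(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2.0 * df["x"]
        table = ols_regression(df, "y", "x", covariates=())
        coef = table.set_index("term").loc["x", "coef"]
        assert coef == pytest.approx(2.0)
        assert table.attrs["r2"] == pytest.approx(1.0)

    def test_simulated_recovery_within_3se(self):
        rng = np.random.default_rng(5)
        n = 500
        df = pd.DataFrame({"x": rng.normal(size=n), "age": rng.normal(70, 5, n)})
        df["y"] = 3.0 + 1.5 * df["x"] - 0.2 * df["age"] + rng.normal(size=n)
        table = ols_regression(df, "y", "x", covariates=("age",)).set_index("term")
        for term, truth in [("const", 3.0), ("x", 1.5), ("age", -0.2)]:
            se = (table.loc[term, "ci_high"] - table.loc[term, "ci_low"]) / (2 * 1.96)
            assert abs(table.loc[term, "coef"] - truth) < 3 * se

    def test_default_covariates_give_five_coefficients(self):
        tab, _ = generate_cohort(CohortSimConfig(n_subjects=40, seed=1))
        table = ols_regression(tab, "anx_change", "swa_log")
        assert len(table) == 5
        assert set(table["term"]) == {"const", "swa_log", "age", "gender", "trait_anxiety"}

    def test_collinear_columns_listed(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"x": rng.normal(size=30)})
        df["x2"] = 2.0 * df["x"]
        df["y"] = df["x"] + rng.normal(size=30)
        with pytest.raises(ValueError, match="x2"):
            ols_regression(df, "y", "x", covariates=("x2",))


class TestPairedT:
    def test_hand_computed(self):
        # differences (1, 2, 3): mean 2, sd 1, t = 2/(1/sqrt(3))
        t, df, ci, p = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert df == 2
        assert ci[0] < 2.0 < ci[1]

    def test_df_is_n_minus_1(self):
        rng = np.random.default_rng(7)
        a = rng.normal(2.3, 0.24, 24)
        b = a - rng.normal(0.15, 0.2, 24)
        _, df, _, _ = paired_t(a, b)
        assert df == 23

    def test_zero_variance_rejected(self):
        x = [1.0, 2.0, 3.0]
        with pytest.raises(ValueError, match="variance"):
            paired_t(x, x)


def brute_force_bh(p):
    """Independent step-up enumeration oracle."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return np.minimum(adjusted, 1.0)


class TestFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_hand_example(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        hst.lists(
            hst.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=10,
        )
    )
    def test_matches_brute_force_enumeration(self, p):
        assert np.allclose(bh_fdr(p), brute_force_bh(p))


class TestMediation:
    def covs(self):
        return ("age", "gender", "trait_anxiety")

    def test_noise_free_exact_product(self):
        # a=2, b=3, c'=0 with deterministic outcomes: indirect exactly 6 and
        # a degenerate (near-point) bootstrap distribution.  M must carry an
        # infinitesimal disturbance orthogonal to (1, x): a mediator that is
        # *exactly* linear in x makes the outcome design rank-deficient.
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        e = rng.normal(size=30)
        Z = np.column_stack([np.ones(30), x])
        e = e - Z @ np.linalg.lstsq(Z, e, rcond=None)[0]  # exactly orthogonal
        m = 1.0 + 2.0 * x + 1e-3 * e
        y = -0.5 + 3.0 * m
        df = pd.DataFrame({"x": x, "m": m, "y": y})
        res = mediation_bootstrap(df, "x", "m", "y", n_boot=200, seed=1)
        assert res.a == pytest.approx(2.0, abs=1e-8)
        assert res.b == pytest.approx(3.0, abs=1e-8)
        assert res.indirect == pytest.approx(6.0, abs=1e-8)
        assert res.ci_low == pytest.approx(6.0, abs=1e-2)
        assert res.ci_high == pytest.approx(6.0, abs=1e-2)

    def test_exact_collinear_mediator_rejected(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=20)
        df = pd.DataFrame({"x": x, "m": 1.0 + 2.0 * x, "y": 3.0 * x})
        with pytest.raises(ValueError, match="rank"):
            mediation_bootstrap(df, "x", "m", "y")

    def test_null_mediation_ci_covers_zero(self):
        cfg = CohortSimConfig(n_subjects=2000, a=0.5, b=0.0, c_prime=1.0, seed=9)
        tab, _ = generate_cohort(cfg)
        res = mediation_bootstrap(
            tab, "atrophy", "swa_log", "anx_change", self.covs(), n_boot=300, seed=2
        )
        assert abs(res.indirect) < 0.5
        assert res.ci_low < 0 < res.ci_high

    def test_linear_identity_total_equals_cprime_plus_ab(self):
        for seed in range(5):
            tab, _ = generate_cohort(CohortSimConfig(n_subjects=60, seed=seed))
            res = mediation_bootstrap(
                tab, "atrophy", "swa_log", "anx_change", self.covs(), n_boot=10, seed=0
            )
            assert res.total == pytest.approx(res.c_prime + res.indirect, rel=1e-8)

    def test_defaults_are_1000_boots_percentile_bounds(self):
        import inspect

        sig = inspect.signature(mediation_bootstrap)
        assert sig.parameters["n_boot"].default == 1000

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        tab, _ = generate_cohort(CohortSimConfig(n_subjects=80, seed=12))
        res = mediation_bootstrap(
            tab, "atrophy", "swa_log", "anx_change", (), n_boot=500, seed=3
        )
        pg = pingouin.mediation_analysis(
            data=tab, x="atrophy", m="swa_log", y="anx_change", n_boot=500, seed=3
        ).set_index("path")
        assert res.indirect == pytest.approx(pg.loc["Indirect", "coef"], rel=1e-6)
        assert res.c_prime == pytest.approx(pg.loc["Direct", "coef"], rel=1e-6)
        assert res.total == pytest.approx(pg.loc["Total", "coef"], rel=1e-6)

    def test_too_few_cases_rejected(self):
        df = pd.DataFrame({"x": range(5), "m": range(5), "y": range(5)}, dtype=float)
        with pytest.raises(ValueError, match="10"):
            mediation_bootstrap(df, "x", "m", "y")

    def test_rank_deficiency_rejected(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame({"x": rng.normal(size=20)})
        df["m"] = rng.normal(size=20)
        df["y"] = rng.normal(size=20)
        df["dup"] = df["x"]
        with pytest.raises(ValueError, match="rank"):
            mediation_bootstrap(df, "x", "m", "y", covariates=("dup",))


def test_log_transform_is_explicit_and_logged():
    df = pd.DataFrame({"v": [1.0, 10.0, 100.0]})
    out = log_transform(df, ("v",))
    assert np.allclose(out["v"], [0.0, 1.0, 2.0])
    assert out.attrs["log_transformed"] == ["v"]
    with pytest.raises(ValueError):
        log_transform(pd.DataFrame({"v": [0.0, 1.0]}), ("v",))
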