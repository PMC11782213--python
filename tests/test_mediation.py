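"""Linear mediation: OLS engine, path estimates, identity, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adcascade.mediation import (
    MediationSpec,
    bootstrap_mediation,
    estimate_mediation,
    fit_ols,
)
from adcascade.synthetic_cohort import generate_cohort

from .conftest import encode_covariates, mediation_recovery_config

# 12-row hand-checkable table; expected paths computed independently via
# pseudo-inverse normal equations (a=1.1, b=0.21875, c'=1.859375)
HAND_TABLE = pd.DataFrame(
    {
        "centiloid": [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11],
        "x1": [1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0],
        "gfap": [2, 3, 5, 4, 7, 8, 9, 8, 12, 11, 14, 13],
        "y": [5, 4, 9, 8, 13, 12, 18, 16, 22, 20, 27, 24],
    },
    dtype=float,
)
HAND_SPEC = MediationSpec(outcome="y", covariates=("x1",))


@pytest.fixture()
def hand_table():
    # replicate to clear the minimum-n guard without changing the fit
    return pd.concat([HAND_TABLE] * 3, ignore_index=True)


class TestFitOls:
    def test_exact_linear_response(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
        beta_true = np.array([1.0, -2.0, 0.5])
        beta, sigma2, _ = fit_ols(X, X @ beta_true)
        assert np.allclose(beta, beta_true)
        assert sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_slope_intercept(self):
        x = np.arange(10.0)
        beta, _, _ = fit_ols(np.column_stack([np.ones(10), x]), 2 * x + 1)
        assert beta == pytest.approx([1.0, 2.0])

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(50), rng.normal(size=(50, 3))])
        y = rng.normal(size=50)
        beta, _, _ = fit_ols(X, y)
        oracle = np.linalg.pinv(X.T @ X) @ X.T @ y  # separately coded route
        assert np.allclose(beta, oracle, atol=1e-8)

    def test_rank_deficiency_names_column(self):
        X = np.column_stack([np.ones(30), np.arange(30.0), 2 * np.arange(30.0)])
        with pytest.raises(ValueError, match="collinear"):
            fit_ols(X, np.zeros(30), column_names=["intercept", "t", "t_copy"])


class TestEstimateMediation:
    def test_hand_table_paths(self, hand_table):
        res = estimate_mediation(HAND_SPEC, hand_table)
        assert res.acme == pytest.approx(1.1 * 0.21875, abs=1e-10)
        assert res.ade == pytest.approx(1.859375, abs=1e-10)
        assert res.total_effect == pytest.approx(2.1, abs=1e-10)
        assert res.proportion_mediated == pytest.approx(0.240625 / 2.1, abs=1e-10)

    def test_identity_acme_plus_ade_is_total(self, hand_table):
        res = estimate_mediation(HAND_SPEC, hand_table)
        assert abs(res.acme + res.ade - res.total_effect) < 1e-10

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_identity_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        df = pd.DataFrame(
            {
                "centiloid": rng.normal(0, 2, n),
                "gfap": rng.normal(0, 2, n),
                "y": rng.normal(0, 2, n),
                "cov": rng.normal(0, 1, n),
            }
        )
        res = estimate_mediation(MediationSpec(outcome="y", covariates=("cov",)), df)
        assert abs(res.acme + res.ade - res.total_effect) < 1e-10
        # total effect equals the treatment coefficient of the reduced model
        X = np.column_stack([np.ones(n), df["centiloid"], df["cov"]])
        reduced = np.linalg.lstsq(X, df["y"], rcond=None)[0][1]
        assert res.total_effect == pytest.approx(reduced, abs=1e-10)

    def test_no_mediation_null(self):
        # b = 0: outcome ignores the mediator
        rng = np.random.default_rng(5)
        n = 1500
        t = rng.normal(0, 2, n)
        m = 0.8 * t + rng.normal(0, 1, n)
        y = 0.5 * t + rng.normal(0, 1, n)
        df = pd.DataFrame({"centiloid": t, "gfap": m, "y": y})
        res = estimate_mediation(MediationSpec(outcome="y", covariates=()), df)
        se_scale = 3 / np.sqrt(n)
        assert abs(res.acme) < 3 * se_scale
        assert abs(res.proportion_mediated) < 0.1

    def test_full_mediation_limit(self):
        rng = np.random.default_rng(6)
        n = 2000
        t = rng.normal(0, 2, n)
        m = 1.0 * t + rng.normal(0, 0.5, n)
        y = 0.9 * m + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"centiloid": t, "gfap": m, "y": y})
        res = estimate_mediation(MediationSpec(outcome="y", covariates=()), df)
        assert res.proportion_mediated == pytest.approx(1.0, abs=0.05)

    def test_mediator_scale_equivariance(self, hand_table):
        scaled = hand_table.copy()
        scaled["gfap"] *= 10.0
        res = estimate_mediation(HAND_SPEC, hand_table)
        res_scaled = estimate_mediation(HAND_SPEC, scaled)
        for attr in ("acme", "ade", "total_effect", "proportion_mediated"):
            assert getattr(res_scaled, attr) == pytest.approx(getattr(res, attr), abs=1e-9)

    def test_minimum_n_enforced(self):
        with pytest.raises(ValueError, match="minimum"):
            estimate_mediation(HAND_SPEC, HAND_TABLE)

    def test_missing_values_rejected(self, hand_table):
        broken = hand_table.copy()
        broken.loc[0, "gfap"] = np.nan
        with pytest.raises(ValueError, match="complete-case"):
            estimate_mediation(HAND_SPEC, broken)


class TestBootstrapMediation:
    def _ds_frame(self, config):
        cohort, _ = generate_cohort(config)
        ds = encode_covariates(cohort[cohort["group"] == "DS"])
        return ds[["centiloid", "gfap", "tau_suvr", "latency_days", "sex_female", "apoe4_carrier"]]

    def test_deterministic_given_seed(self):
        df = self._ds_frame(mediation_recovery_config(3, 0.5, 0.4, 0.3, n_ds=150))
        spec = MediationSpec(outcome="tau_suvr", n_bootstrap=200, seed=9)
        r1 = bootstrap_mediation(spec, df)
        r2 = bootstrap_mediation(spec, df)
        assert r1.ci == r2.ci and r1.p_values == r2.p_values

    def test_recovers_configured_proportion(self):
        df = self._ds_frame(mediation_recovery_config(0, 0.5, 0.4, 0.3))
        spec = MediationSpec(outcome="tau_suvr", n_bootstrap=300, seed=1)
        res = bootstrap_mediation(spec, df)
        assert res.proportion_mediated == pytest.approx(0.4, abs=0.1)
        lo, hi = res.ci["proportion_mediated"]
        assert lo < res.proportion_mediated < hi

    def test_statsmodels_cross_check(self):
        import statsmodels.api as sm
        from statsmodels.stats.mediation import Mediation

        rng = np.random.default_rng(7)
        n = 800
        t = rng.normal(0, 2, n)
        m = 1.2 * t + rng.normal(0, 1, n)
        y = 0.5 * t + 0.8 * m + rng.normal(0, 1, n)
        df = pd.DataFrame({"centiloid": t, "gfap": m, "out": y})
        mine = estimate_mediation(MediationSpec(outcome="out", covariates=()), df)
        med = Mediation(
            sm.OLS.from_formula("out ~ centiloid + gfap", df),
            sm.OLS.from_formula("gfap ~ centiloid", df),
            "centiloid",
            "gfap",
        ).fit(n_rep=200)
        summary = med.summary()
        assert mine.acme == pytest.approx(summary.loc["ACME (average)", "Estimate"], rel=0.05)
        assert mine.ade == pytest.approx(summary.loc["ADE (average)", "Estimate"], rel=0.05)

    def test_conclusions_robust_to_apoe_covariate(self, default_cohort):
        cohort, _ = default_cohort
        ds = encode_covariates(cohort[cohort["group"] == "DS"]).dropna(
            subset=["centiloid", "gfap", "ptau217"]
        )
        cols = ["centiloid", "gfap", "ptau217", "latency_days", "sex_female", "apoe4_carrier"]
        with_apoe = bootstrap_mediation(
            MediationSpec(outcome="ptau217", n_bootstrap=300, seed=2), ds[cols]
        )
        without_apoe = bootstrap_mediation(
            MediationSpec(
                outcome="ptau217",
                covariates=("latency_days", "sex_female"),
                n_bootstrap=300,
                seed=2,
            ),
            ds[cols],
        )
        assert np.sign(with_apoe.acme) == np.sign(without_apoe.acme)
        assert (with_apoe.p_values["acme"] < 0.05) == (without_apoe.p_values["acme"] < 0.05)
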