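"""Component regressions: recovery, diagnostics, nesting, categorical fits."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from hunt_mediation.design import build_design, resolve_levels
from hunt_mediation.regression import (
    fit_categorical_model,
    fit_linear,
    lrt_spline_vs_linear,
    wald_joint_test,
)
from hunt_mediation.specs import MediationSpec
from hunt_mediation.splines import rcs_basis
from hunt_mediation.synthetic import generate_cohort

from conftest import make_linear_config


def _frame(n, seed=0, y=None):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "wave": rng.integers(0, 2, n),
            "sex": rng.integers(0, 2, n),
            "age": rng.uniform(20, 101, n),
            "education": rng.integers(1, 5, n),
            "ht_low": np.zeros(n),
        }
    )
    if y is not None:
        df["ht_low"] = y(df, rng)
    return df


def test_ols_recovers_known_wave_effect():
    df = _frame(10_000, y=lambda d, rng: 3 - 2 * d["wave"] + rng.normal(0, 1, len(d)))
    fit = fit_linear(df, "ht_low", ["1", "wave", "sex", "rcs(age)"],
                     spline=rcs_basis(df["age"]))
    se = np.sqrt(fit.cov[fit.names.index("wave"), fit.names.index("wave")])
    assert abs(fit.coef("wave") + 2.0) < 3 * se


def test_constant_outcome_gives_zero_slopes():
    df = _frame(500)
    df["ht_low"] = 7.25
    fit = fit_linear(df, "ht_low", ["1", "wave", "sex"], spline=None)
    assert abs(fit.coef("Intercept") - 7.25) < 1e-8
    assert abs(fit.coef("wave")) < 1e-8 and abs(fit.coef("sex")) < 1e-8


def test_duplicate_column_raises_rank_error():
    df = _frame(200)
    with pytest.raises(ValueError, match="collinear"):
        fit_linear(df, "ht_low", ["1", "wave", "wave"], spline=None)


def test_ols_residuals_orthogonal_to_design():
    df = _frame(3000, y=lambda d, rng: d["age"] * 0.2 + rng.normal(0, 2, len(d)))
    spline = rcs_basis(df["age"])
    fit = fit_linear(df, "ht_low", ["1", "wave", "sex", "rcs(age)"], spline=spline)
    X, _ = build_design(df, fit.terms, spline=spline, levels=fit.levels)
    resid = df["ht_low"].to_numpy() - fit.predict(df)
    assert np.abs(X.T @ resid).max() / len(df) < 1e-8


def test_categorical_null_model_slopes_near_zero():
    # note: a distinct seed keeps the target independent of the wave column
    rng = np.random.default_rng(99)
    df = _frame(8000, seed=1)
    df["smoking"] = rng.integers(1, 4, len(df)).astype(float)
    fit = fit_categorical_model(df, "smoking", ["1", "wave"], spline=None)
    se = np.sqrt(np.clip(np.diag(fit.cov), 0, None)).reshape(fit.params.shape[1], -1).T
    wave_row = fit.names.index("wave")
    assert np.all(np.abs(fit.params[wave_row]) < 3 * se[wave_row] + 1e-9)


def test_categorical_recovers_logit_slope_and_matches_statsmodels():
    rng = np.random.default_rng(2)
    n = 20_000
    df = _frame(n, seed=2)
    eta = -0.4 + 1.2 * df["wave"].to_numpy()
    df["ear_infections"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float) + 1
    fit = fit_categorical_model(df, "ear_infections", ["1", "wave"], spline=None)
    slope = fit.params[fit.names.index("wave"), 0]
    se = np.sqrt(fit.cov[1, 1])
    assert abs(slope - 1.2) < 3 * se
    # independent route: statsmodels MNLogit on the same design
    X, _ = build_design(df, ["1", "wave"], levels=resolve_levels(df))
    res = sm.MNLogit((df["ear_infections"] - 1).to_numpy(int), X).fit(disp=0)
    assert np.abs(fit.params - res.params).max() < 1e-4
    assert abs(fit.loglik - res.llf) < 1e-4


def test_categorical_probabilities_normalized(hunt_data_small):
    df = hunt_data_small.dropna(subset=["noise"]).reset_index(drop=True)
    fit = fit_categorical_model(
        df, "noise", ["1", "wave", "sex", "C(education)", "rcs(age)"],
        spline=rcs_basis(df["age"]),
    )
    probs = fit.predict_proba(df)
    assert probs.min() >= 0 and probs.max() <= 1
    assert np.abs(probs.sum(axis=1) - 1).max() < 1e-10


def test_categorical_requires_two_levels():
    df = _frame(100)
    df["smoking"] = 1.0
    with pytest.raises(ValueError, match="fewer than 2"):
        fit_categorical_model(df, "smoking", ["1", "wave"], spline=None)


def test_wald_joint_test_on_null_terms():
    df = _frame(5000, y=lambda d, rng: rng.normal(0, 1, len(d)))
    fit = fit_linear(df, "ht_low", ["1", "wave", "sex"], spline=None)
    stat, dof, p = wald_joint_test(fit, ["wave", "sex"])
    assert dof == 2 and stat >= 0 and 0 < p <= 1


class TestSplineVsLinearLRT:
    def test_statistic_nonnegative_and_nesting(self, linear_data_mid):
        spec = MediationSpec(outcome="ht_low", mediators=("ear_infections",))
        stat, dof, p = lrt_spline_vs_linear(linear_data_mid, spec)
        assert stat >= 0 and dof == 3 and 0 < p <= 1

    def test_type_i_error_near_nominal(self):
        """Linear-age generator: the 5%-level LRT rejects ~5% of the time."""
        cfg = make_linear_config(1000)
        spec = MediationSpec(outcome="ht_low", mediators=("ear_infections",))
        reject = 0
        n_rep = 500
        for s in range(n_rep):
            df = generate_cohort(cfg, seed=10_000 + s)
            _, _, p = lrt_spline_vs_linear(df, spec)
            reject += p < 0.05
        assert 0.03 <= reject / n_rep <= 0.07

    def test_power_against_curved_age_effect(self):
        """Strongly curved age effect: LRT p < 0.001 essentially always."""
        cfg = make_linear_config(2500)
        out = cfg.outcome_models["ht_low"]
        out.coef["age_rcs"] = np.array([0.3, 3.0, -6.0, 3.5])
        spec = MediationSpec(outcome="ht_low", mediators=("ear_infections",))
        hits = sum(
            lrt_spline_vs_linear(generate_cohort(cfg, seed=20_000 + s), spec)[2] < 1e-3
            for s in range(20)
        )
        assert hits >= 19
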