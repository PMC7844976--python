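"""Bootstrap inference and the residual-correlation sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from hunt_mediation.sensitivity import bootstrap_ci, sensitivity_rho
from hunt_mediation.specs import MediationSpec
from hunt_mediation.synthetic import generate_cohort

from conftest import make_linear_config


class TestBootstrap:
    def test_se_matches_closed_form_for_sample_mean(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"v": rng.normal(0, 8.0, 1000)})
        boot = bootstrap_ci(lambda d: d["v"].mean(), df, n_draws=1000, seed=1)
        analytic = df["v"].std(ddof=1) / np.sqrt(len(df))
        assert abs(boot["se"] - analytic) / analytic < 0.15

    def test_constant_estimator_degenerate_ci(self):
        df = pd.DataFrame({"v": np.arange(50.0)})
        boot = bootstrap_ci(lambda d: 3.5, df, n_draws=100, seed=2)
        assert boot["se"] == 0.0
        assert boot["ci_low"] == boot["ci_high"] == 3.5

    def test_identical_seed_reproducible(self, linear_data_mid):
        f = lambda d: d["ht_low"].mean()  # noqa: E731
        a = bootstrap_ci(f, linear_data_mid, n_draws=50, seed=9)
        b = bootstrap_ci(f, linear_data_mid, n_draws=50, seed=9)
        assert a == b

    def test_failing_estimator_aborts_with_log(self):
        df = pd.DataFrame({"v": np.arange(20.0)})

        def flaky(d):
            if d["v"].iloc[0] != 0.0:  # fails on almost every resample
                raise RuntimeError("boom")
            return 1.0

        with pytest.raises(RuntimeError, match="resamples"):
            bootstrap_ci(flaky, df, n_draws=100, seed=3)

    def test_too_few_draws_rejected(self, linear_data_mid):
        with pytest.raises(ValueError, match="n_draws"):
            bootstrap_ci(lambda d: 0.0, linear_data_mid, n_draws=1)


def _confounded_cohort(n, *, a=0.6, lam_m=0.6, s_m=1.0, lam_y=2.0, s_y=6.0, seed=5):
    """No true mediation; a shared latent U drives both mediator and outcome.

    The binary mediator is a probit threshold of a*wave + lam_m*U + eps_m,
    so the residual correlation with the outcome error lam_y*U + eps_y has
    a closed form (returned alongside the table).
    """
    rng = np.random.default_rng(seed)
    wave = rng.integers(0, 2, n)
    age = rng.uniform(20, 101, n)
    sex = rng.integers(0, 2, n)
    U = rng.normal(size=n)
    m_star = a * wave + lam_m * U + rng.normal(0, s_m, n)
    med = (m_star > 0).astype(float) + 1
    y = 3.0 - 1.0 * wave + lam_y * U + rng.normal(0, s_y, n)
    df = pd.DataFrame(
        {
            "subject_id": [str(i) for i in range(n)],
            "wave": wave, "age": age, "sex": sex,
            "education": np.ones(n, dtype=int),
            "noise": np.ones(n), "ear_infections": med, "smoking": np.ones(n),
            "ht_low": y, "ht_high": y,
        }
    )
    # closed form: per wave w, latent scale s = sqrt(lam_m^2 + s_m^2),
    # p_w = Phi(a w / s), cov(M, U | w) = (lam_m / s) phi(a w / s)
    s = np.hypot(lam_m, s_m)
    p = norm.cdf(np.array([0.0, a]) / s)
    cov_mu = (lam_m / s) * norm.pdf(np.array([0.0, a]) / s)
    sigma_m = np.sqrt(np.mean(p * (1 - p)))
    sigma_y = np.hypot(lam_y, s_y)
    r_star = lam_y * np.mean(cov_mu) / (sigma_m * sigma_y)
    return df, float(r_star)


class TestSensitivityRho:
    SPEC = MediationSpec(outcome="ht_low", mediators=("ear_infections",))

    def test_rho_zero_recovers_closed_form_residual_correlation(self):
        df, r_star = _confounded_cohort(60_000)
        curve = sensitivity_rho(df, self.SPEC)
        assert curve.rho_zero is not None
        assert abs(curve.rho_zero - r_star) < 0.02

    def test_rho_zero_equals_primary_estimate(self, linear_data_mid):
        curve = sensitivity_rho(linear_data_mid, self.SPEC)
        assert curve.nie(0.0) == pytest.approx(curve.nie_ref, abs=1e-8)
        # independent route: product of the two OLS path coefficients
        import statsmodels.api as sm

        from hunt_mediation.design import build_design, resolve_levels
        from hunt_mediation.splines import rcs_basis

        spline = rcs_basis(linear_data_mid["age"])
        levels = resolve_levels(linear_data_mid)
        Xm, _ = build_design(linear_data_mid, ["1", "wave", "sex", "rcs(age)"],
                             spline=spline, levels=levels)
        a = sm.OLS(linear_data_mid["ear_infections"].to_numpy(float), Xm).fit().params[1]
        Xy = np.column_stack([Xm, linear_data_mid["ear_infections"].to_numpy(float)])
        b = sm.OLS(linear_data_mid["ht_low"].to_numpy(), Xy).fit().params[-1]
        assert curve.nie_ref == pytest.approx(a * b, abs=1e-8)

    def test_true_mediation_gives_nonzero_curve(self, linear_data_mid):
        curve = sensitivity_rho(linear_data_mid, self.SPEC)
        assert abs(curve.nie(0.0)) > 0
        assert curve.rho_zero is None or abs(curve.rho_zero) > 0.01

    def test_curve_continuous_on_grid(self, linear_data_mid):
        curve = sensitivity_rho(linear_data_mid, self.SPEC)
        jumps = np.abs(np.diff(curve.nie_at_rho))
        step = np.diff(curve.rho_grid)[0]
        slope = np.median(jumps) / step
        assert jumps.max() < 5 * step * max(slope, 1e-12) + 1e-12

    @pytest.mark.parametrize("grid", [np.array([-1.0, 0.0]), np.array([0.2, 0.1])])
    def test_invalid_grid_rejected(self, linear_data_mid, grid):
        with pytest.raises(ValueError):
            sensitivity_rho(linear_data_mid, self.SPEC, rho_grid=grid)
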