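"""Parametric G-computation: oracles, coherence, assumption selection."""

import numpy as np
import pytest

from hunt_mediation.gformula import (
    GFormulaConfig,
    gformula_specific_nie,
    partial_nie_education,
)
from hunt_mediation.gformula import (
    test_identification_assumptions as check_identification_assumptions,
)
from hunt_mediation.synthetic import MediatorModel
from hunt_mediation.natural_effects import estimate_joint_nie
from hunt_mediation.regression import fit_linear
from hunt_mediation.sensitivity import bootstrap_ci
from hunt_mediation.specs import MediationSpec
from hunt_mediation.splines import rcs_basis
from hunt_mediation.synthetic import generate_cohort, true_effects

from conftest import make_linear_config


def l_path_config(n_per_wave, *, edu_beta=(1.0, 2.0, 3.0), med_to_y=-2.0):
    """Exposure shifts education (score +0.4) and a binary mediator (dp = 0.3).

    Education enters the outcome linearly in its score and does not affect
    the mediator, so the mediator-specific NIE is dp x beta_M = -0.6 under
    the linear-confounder identification.
    """
    b0 = float(np.log(0.35 / 0.65))
    b1 = float(np.log(0.65 / 0.35)) - b0   # expit(b0+b1)=0.65, expit(b0)=0.35
    cfg = make_linear_config(
        n_per_wave, med_intercept=b0, med_wave=b1, beta_m=med_to_y, direct=-1.0
    )
    cfg.education_probs = {
        (0, s): np.array([0.4, 0.3, 0.2, 0.1]) for s in (0, 1)
    } | {(1, s): np.array([0.25, 0.3, 0.25, 0.2]) for s in (0, 1)}
    cfg.outcome_models["ht_low"].coef["education"] = np.asarray(edu_beta, dtype=float)
    return with_comediators(cfg)


def with_comediators(cfg):
    """Add binary noise/smoking mediators independent of education."""
    for name, b1 in (("noise", 0.3), ("smoking", -0.2)):
        cfg.mediator_models[name] = MediatorModel(
            levels=2, coef={"intercept": np.array([-0.5]), "wave": np.array([b1])}
        )
    return cfg


SPEC_NO_L = MediationSpec(outcome="ht_low", mediators=("ear_infections",))
SPEC_L = MediationSpec(
    outcome="ht_low", mediators=("ear_infections",),
    intermediate_confounder="education", identification="linear_L_effect",
)


def test_path_tracing_oracle_with_intermediate_confounder():
    cfg = l_path_config(10_000)
    assert true_effects(cfg, "ht_low").nie_by_mediator["ear_infections"] == \
        pytest.approx(-0.6, abs=1e-9)
    df = generate_cohort(cfg, seed=1)
    boot = bootstrap_ci(
        lambda d: gformula_specific_nie(d, SPEC_L, GFormulaConfig(20_000, seed=5)).nie,
        df, n_draws=60, seed=2,
    )
    assert abs(boot["point"] + 0.6) < 2 * boot["se"]


def test_agrees_with_joint_estimator_when_no_confounder(linear_data_mid):
    """Single mediator, no L: g-formula and the natural effect model coincide."""
    boot = bootstrap_ci(
        lambda d: gformula_specific_nie(d, SPEC_NO_L, GFormulaConfig(20_000, seed=3)).nie
        - estimate_joint_nie(d, SPEC_NO_L).nie,
        linear_data_mid, n_draws=60, seed=0,
    )
    assert abs(boot["point"]) < 2 * max(boot["se"], 0.01)


def test_seeded_runs_bit_identical(linear_data_mid):
    a = gformula_specific_nie(linear_data_mid, SPEC_NO_L, GFormulaConfig(5000, seed=9))
    b = gformula_specific_nie(linear_data_mid, SPEC_NO_L, GFormulaConfig(5000, seed=9))
    assert a.nie == b.nie and a.total_effect == b.total_effect


def test_mc_error_scales_as_inverse_sqrt(linear_data_mid):
    errs = [
        gformula_specific_nie(
            linear_data_mid, SPEC_NO_L, GFormulaConfig(R, seed=4)
        ).mc_error
        for R in (2000, 8000, 32_000)
    ]
    for a, b in zip(errs, errs[1:]):
        assert 1.4 < a / b < 2.9  # nominal ratio 2 per 4x replicates


def test_total_effect_coherent_with_adjusted_regression(linear_data_mid):
    """G-formula total reproduces the covariate-adjusted cohort effect."""
    g = gformula_specific_nie(linear_data_mid, SPEC_NO_L, GFormulaConfig(100_000, seed=0))
    # the unmediated-model wave coefficient is the regression total effect
    fit_tot = fit_linear(
        linear_data_mid, "ht_low", ["1", "wave", "sex", "rcs(age)"],
        spline=rcs_basis(linear_data_mid["age"]),
    )
    i = fit_tot.names.index("wave")
    se = np.sqrt(fit_tot.cov[i, i])
    assert abs(g.total_effect - fit_tot.coef("wave")) < 3 * se


class TestPartialEducation:
    def test_oracle_no_downstream_leakage(self):
        cfg = l_path_config(10_000, edu_beta=(-1.0, -2.0, -3.0), med_to_y=0.0)
        # exposure shifts the education score by +0.4; -1 dB per score unit
        df = generate_cohort(cfg, seed=6)
        spec = MediationSpec(outcome="ht_low", mediators=("education",))
        boot = bootstrap_ci(
            lambda d: partial_nie_education(
                d, spec, "noise", GFormulaConfig(20_000, seed=1)
            ).nie,
            df, n_draws=60, seed=3,
        )
        assert abs(boot["point"] + 0.4) < 2 * boot["se"]

    @pytest.fixture()
    def inert_education_data(self):
        # education has identical laws in both waves and no outcome effect
        cfg = with_comediators(make_linear_config(6000))
        return generate_cohort(cfg, seed=12)

    def test_null_when_education_affects_nothing(self, inert_education_data):
        spec = MediationSpec(outcome="ht_low", mediators=("education",))
        boot = bootstrap_ci(
            lambda d: partial_nie_education(
                d, spec, "noise", GFormulaConfig(10_000, seed=2)
            ).nie,
            inert_education_data, n_draws=60, seed=4,
        )
        assert abs(boot["point"]) < 3 * max(boot["se"], 1e-6)

    def test_control_choice_irrelevant_when_independent(self, inert_education_data):
        spec = MediationSpec(outcome="ht_low", mediators=("education",))
        boot = bootstrap_ci(
            lambda d: partial_nie_education(d, spec, "noise", GFormulaConfig(8000, seed=1)).nie
            - partial_nie_education(d, spec, "smoking", GFormulaConfig(8000, seed=1)).nie,
            inert_education_data, n_draws=50, seed=5,
        )
        assert abs(boot["point"]) < 2 * max(boot["se"], 0.01)

    def test_bad_control_rejected(self, inert_education_data):
        spec = MediationSpec(outcome="ht_low", mediators=("education",))
        with pytest.raises(ValueError, match="control"):
            partial_nie_education(inert_education_data, spec, "age", GFormulaConfig(1000))


def test_identification_strategies_agree_when_both_hold(hunt_data_small):
    """Default generator satisfies both assumptions; estimates must agree."""
    df = hunt_data_small.dropna().reset_index(drop=True)
    spec_a = MediationSpec(
        outcome="ht_low", mediators=("noise",), intermediate_confounder="education",
        identification="no_XM_interaction", interactions=False,
    )
    spec_b = MediationSpec(
        outcome="ht_low", mediators=("noise",), intermediate_confounder="education",
        identification="linear_L_effect",
    )
    boot = bootstrap_ci(
        lambda d: gformula_specific_nie(d, spec_a, GFormulaConfig(8000, seed=1)).nie
        - gformula_specific_nie(d, spec_b, GFormulaConfig(8000, seed=1)).nie,
        df, n_draws=50, seed=6,
    )
    assert abs(boot["point"]) < 2 * max(boot["se"], 0.01)


class TestAssumptionSelection:
    def test_report_structure(self, hunt_data_small):
        df = hunt_data_small.dropna().reset_index(drop=True)
        spec = MediationSpec(
            outcome="ht_low", mediators=("ear_infections", "noise", "smoking"),
            intermediate_confounder="education",
        )
        rep = check_identification_assumptions(df, spec)
        expected = {
            "exposure_x_ear_infections", "exposure_x_noise", "exposure_x_smoking",
            "exposure_x_mediators_joint", "exposure_x_education",
            "nonlinearity_education",
        }
        assert set(rep.tests) == expected
        assert rep.recommended in ("no_XM_interaction", "linear_L_effect")

    def test_detects_strong_interaction_and_recommends_linear_l(self):
        from hunt_mediation.synthetic import hunt_default_config

        cfg = hunt_default_config(n_per_wave=10_000, missingness_rate=0.0)
        cfg.outcome_models["ht_low"].coef["wave:noise"] = np.array([1.0, 1.5, 2.0])
        df = generate_cohort(cfg, seed=8)
        spec = MediationSpec(
            outcome="ht_low", mediators=("ear_infections", "noise", "smoking"),
            intermediate_confounder="education",
        )
        rep = check_identification_assumptions(df, spec)
        assert rep.tests["exposure_x_noise"][2] < 1e-6
        assert rep.recommended == "linear_L_effect"


@pytest.mark.parametrize(
    "bad",
    [
        lambda: GFormulaConfig(0),
        lambda: GFormulaConfig(1000, identification="nope"),
    ],
)
def test_config_validation(bad):
    with pytest.raises(ValueError):
        bad()


def test_missing_identification_with_confounder_rejected(linear_data_mid):
    spec = MediationSpec(
        outcome="ht_low", mediators=("ear_infections",),
        intermediate_confounder="education", identification="none_required",
    )
    with pytest.raises(ValueError, match="identification"):
        gformula_specific_nie(linear_data_mid, spec, GFormulaConfig(1000))


def test_small_mc_flagged(linear_data_mid):
    r = gformula_specific_nie(linear_data_mid, SPEC_NO_L, GFormulaConfig(500, seed=0))
    assert any("below 1000" in n for n in r.notes)
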