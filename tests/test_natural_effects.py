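"""Imputation-based natural effect model and the difference-method comparator."""

import numpy as np
import pytest

from hunt_mediation.natural_effects import (
    difference_method,
    estimate_joint_nie,
    mediated_proportion,
)
from hunt_mediation.sensitivity import bootstrap_ci
from hunt_mediation.specs import MediationResult, MediationSpec
from hunt_mediation.synthetic import generate_cohort

from conftest import linear_closed_form_nie, make_linear_config

SPEC1 = MediationSpec(outcome="ht_low", mediators=("ear_infections",))
SPEC4 = MediationSpec(
    outcome="ht_low", mediators=("education", "ear_infections", "noise", "smoking")
)


def test_nie_null_when_mediator_independent_of_exposure():
    cfg = make_linear_config(10_000, med_wave=0.0)
    df = generate_cohort(cfg, seed=1)
    boot = bootstrap_ci(lambda d: estimate_joint_nie(d, SPEC1).nie, df,
                        n_draws=100, seed=0)
    assert abs(boot["point"]) < 3 * boot["se"]


def test_product_of_coefficients_oracle():
    """Mean estimate over 5 cohorts within 2 SEs (of the mean) of a·b."""
    cfg = make_linear_config(20_000)
    df0 = generate_cohort(cfg, seed=2)
    se = bootstrap_ci(lambda d: estimate_joint_nie(d, SPEC1).nie, df0,
                      n_draws=100, seed=0)["se"]
    ests = [
        estimate_joint_nie(generate_cohort(cfg, seed=200 + s), SPEC1).nie
        for s in range(5)
    ]
    assert abs(np.mean(ests) - linear_closed_form_nie()) < 2 * se / np.sqrt(5)


@pytest.mark.parametrize("seed", [0, 1])
def test_decomposition_identity(hunt_data_small, seed):
    df = generate_cohort(make_linear_config(2000, missingness=0.0, seed=seed))
    r = estimate_joint_nie(df, SPEC1)
    assert abs(r.nde + r.nie - r.total_effect) < 1e-8
    hunt = hunt_data_small.dropna().reset_index(drop=True)
    r2 = estimate_joint_nie(hunt, SPEC4)
    assert abs(r2.nde + r2.nie - r2.total_effect) < 1e-8


def test_difference_method_agrees_in_linear_system(linear_data_mid):
    r_imp = estimate_joint_nie(linear_data_mid, SPEC1)
    r_diff = difference_method(linear_data_mid, SPEC1)
    assert abs(r_imp.nie - r_diff.nie) < 0.05
    boot = bootstrap_ci(lambda d: difference_method(d, SPEC1).nie, linear_data_mid,
                        n_draws=100, seed=0)
    assert abs(boot["point"] - linear_closed_form_nie()) < 2 * boot["se"]


def test_difference_method_diverges_under_interaction():
    """A large exposure x mediator interaction splits the two estimators.

    With heterogeneous mediator prevalence the additive-model exposure
    coefficient no longer equals the counterfactual direct effect; the gap
    between the estimators is judged against the bootstrap SE of the paired
    difference (the estimators are highly correlated on the same data).
    """
    cfg = make_linear_config(20_000, interaction=3.0, residual_sd=2.0)
    cfg.mediator_models["ear_infections"].coef["sex"] = np.array([2.5])
    df = generate_cohort(cfg, seed=3)
    boot = bootstrap_ci(
        lambda d: estimate_joint_nie(d, SPEC1).nie - difference_method(d, SPEC1).nie,
        df, n_draws=60, seed=0,
    )
    assert abs(boot["point"]) > 3 * boot["se"]


def test_exposure_must_be_binary(linear_data_mid):
    df = linear_data_mid.copy()
    df.loc[df.index[:10], "wave"] = 2
    with pytest.raises(ValueError, match="binary"):
        estimate_joint_nie(df, SPEC1)


def test_missing_mediator_column_rejected(linear_data_mid):
    df = linear_data_mid.drop(columns=["smoking"])
    spec = MediationSpec(outcome="ht_low", mediators=("smoking",))
    with pytest.raises(ValueError, match="absent"):
        estimate_joint_nie(df, spec)


class TestMediatedProportion:
    @pytest.mark.parametrize(
        "total, nie, rounded",
        [(-2.79, -0.76, 0.27), (-2.97, -0.82, 0.28), (-5.0, 0.0, 0.0)],
    )
    def test_table_style_rounding(self, total, nie, rounded):
        assert round(mediated_proportion(total, nie), 2) == rounded

    def test_null_total_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            mediated_proportion(0.0, -0.5)


def test_result_ci_must_bracket_point():
    with pytest.raises(ValueError, match="bracket"):
        MediationResult(
            total_effect=-2.0, nde=-1.5, nie=-0.5, mediated_proportion=0.25,
            method="m", stratum="all", n_used=10, ci={"nie": (0.1, 0.2)},
        )
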