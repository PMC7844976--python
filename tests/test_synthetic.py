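"""Generator calibration, reproducibility and analytic true effects."""

import numpy as np
import pytest

from hunt_mediation.synthetic import (
    GeneratorConfig,
    config_from_dict,
    config_to_dict,
    generate_cohort,
    hunt_default_config,
    true_effects,
)

from conftest import linear_closed_form_nie, make_linear_config


def test_identical_seed_and_config_bit_identical(hunt_config_small):
    a = generate_cohort(hunt_config_small, seed=5)
    b = generate_cohort(hunt_config_small, seed=5)
    assert a.equals(b)
    c = generate_cohort(hunt_config_small, seed=6)
    assert not a.equals(c)


def test_marginal_calibration_at_large_n():
    """Configured cell marginals reproduced within 3 binomial SEs at n=100k."""
    cfg = hunt_default_config(n_per_wave=100_000, missingness_rate=0.0)
    df = generate_cohort(cfg, seed=11)
    checks = [
        # (wave, sex, column, level, target from the published distribution)
        (1, 0, "smoking", 3, 0.09),
        (0, 1, "noise", 4, 0.25 / 0.99),
        (1, 1, "ear_infections", 1, 0.85),
        (0, 0, "education", 2, 0.48 / 0.99),
    ]
    for w, s, col, level, target in checks:
        cell = df[(df.wave == w) & (df.sex == s)]
        p_hat = (cell[col] == level).mean()
        tol = 3 * np.sqrt(target * (1 - target) / len(cell))
        assert abs(p_hat - target) < tol, (col, w, s, p_hat, target)


def test_age_and_sex_marginals(hunt_config_small):
    df = generate_cohort(hunt_default_config(n_per_wave=30_000), seed=2)
    h2, h4 = df[df.wave == 0], df[df.wave == 1]
    assert df.age.between(20, 101).all()
    assert abs(h2.age.mean() - 50.1) < 0.4 and abs(h4.age.mean() - 53.2) < 0.4
    assert abs((h2.sex == 0).mean() - 0.53) < 0.01
    assert abs((h4.sex == 0).mean() - 0.56) < 0.01


def test_missingness_only_on_mediators():
    cfg = hunt_default_config(n_per_wave=20_000, missingness_rate=0.09)
    df = generate_cohort(cfg, seed=4)
    frac = df[["noise", "ear_infections", "smoking"]].isna().any(axis=1).mean()
    assert abs(frac - 0.09) < 0.01
    assert df[["wave", "age", "sex", "education", "ht_low", "ht_high"]].notna().all().all()


@pytest.mark.parametrize(
    "mutate, match",
    [
        (lambda d: d.update(n_per_wave=0), "n_per_wave"),
        (lambda d: d["education_probs"].update({"0,0": [0.5, 0.5, 0.1, 0.1]}),
         "education_probs"),
        (lambda d: d["outcome_models"]["ht_low"].update(residual_sd=-1.0),
         "residual_sd"),
        (lambda d: d["mediator_models"]["ear_infections"]["coef"].update(
            wave=[np.inf]), "non-finite"),
        (lambda d: d.update(missingness_rate=1.5), "missingness_rate"),
    ],
)
def test_config_validation_names_offending_field(mutate, match):
    d = config_to_dict(make_linear_config(100))
    mutate(d)
    with pytest.raises((ValueError,), match=match):
        config_from_dict(d)


def test_config_dict_roundtrip(hunt_config_small):
    d = config_to_dict(hunt_config_small)
    cfg2 = config_from_dict(d)
    a = generate_cohort(hunt_config_small, seed=9)
    b = generate_cohort(cfg2, seed=9)
    assert a.equals(b)


class TestTrueEffects:
    def test_all_wave_coefficients_zero_gives_null_effects(self):
        cfg = make_linear_config(100, med_wave=0.0, direct=0.0)
        te = true_effects(cfg, "ht_low")
        assert te.total == pytest.approx(0.0, abs=1e-10)
        assert te.nde == pytest.approx(0.0, abs=1e-10)
        assert te.nie_joint == pytest.approx(0.0, abs=1e-10)

    def test_decomposition_identity_exact(self, hunt_config_small):
        te = true_effects(hunt_config_small, "ht_high")
        assert te.nde + te.nie_joint - te.total == pytest.approx(0.0, abs=1e-12)

    def test_specific_effects_sum_to_joint_without_interactions(self, hunt_config_small):
        te = true_effects(hunt_config_small, "ht_low")
        assert sum(te.nie_by_mediator.values()) == pytest.approx(te.nie_joint, abs=1e-9)

    def test_closed_form_single_mediator(self):
        cfg = make_linear_config(100)
        te = true_effects(cfg, "ht_low")
        assert te.nie_joint == pytest.approx(linear_closed_form_nie(), abs=1e-9)
        assert te.nde == pytest.approx(-1.0, abs=1e-9)

    def test_interactions_flagged_and_identity_still_exact(self):
        cfg = make_linear_config(100, interaction=1.0)
        te = true_effects(cfg, "ht_low")
        assert te.derivation["interactions_present"]
        assert te.nde + te.nie_joint - te.total == pytest.approx(0.0, abs=1e-12)
        # interaction at exposure 1 scales the mediator path: (beta + tau) * dp
        expected = linear_closed_form_nie(beta_m=3.0)
        assert te.nie_joint == pytest.approx(expected, abs=1e-9)

    def test_quadrature_error_reported_small(self, hunt_config_small):
        te = true_effects(hunt_config_small, "ht_low")
        assert te.quadrature_error < 1e-6
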