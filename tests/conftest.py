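"""Shared fixtures: small generator configurations with known truths."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import expit

from hunt_mediation.synthetic import (
    AgeDist,
    GeneratorConfig,
    MediatorModel,
    OutcomeModel,
    generate_cohort,
    hunt_default_config,
)


def make_linear_config(
    n_per_wave: int,
    *,
    med_wave: float = 0.9,
    med_intercept: float = -0.3,
    beta_m: float = 2.0,
    direct: float = -1.0,
    interaction: float = 0.0,
    residual_sd: float = 4.0,
    missingness: float = 0.0,
    seed: int = 0,
) -> GeneratorConfig:
    """Single binary mediator, linear Gaussian outcome, optional X x M term.

    The mediator (stored in the ear-infections column, levels 1/2) follows a
    logit in the wave only, so the closed-form joint NIE is
    ``beta_m * (expit(b0 + b1) - expit(b0))`` when no interaction is present.
    """
    mm = MediatorModel(
        levels=2,
        coef={"intercept": np.array([med_intercept]), "wave": np.array([med_wave])},
    )
    coef = {
        "intercept": 5.0,
        "wave": direct,
        "sex": 0.3,
        "ear_infections": np.array([beta_m]),
        "age_rcs": np.array([0.05, 0.0, 0.0, 0.0]),
    }
    if interaction != 0.0:
        coef["wave:ear_infections"] = np.array([interaction])
    out = OutcomeModel(coef=coef, residual_sd=residual_sd)
    edu = {(w, s): np.array([0.4, 0.3, 0.2, 0.1]) for w in (0, 1) for s in (0, 1)}
    return GeneratorConfig(
        n_per_wave=n_per_wave,
        age_dist={0: AgeDist(50.0, 17.0), 1: AgeDist(50.0, 17.0)},
        p_female={0: 0.5, 1: 0.5},
        education_probs=edu,
        mediator_models={"ear_infections": mm},
        outcome_models={"ht_low": out, "ht_high": out},
        missingness_rate=missingness,
        seed=seed,
    )


def linear_closed_form_nie(
    med_intercept: float = -0.3, med_wave: float = 0.9, beta_m: float = 2.0
) -> float:
    """Product-of-coefficients truth for the linear single-mediator config."""
    return beta_m * (expit(med_intercept + med_wave) - expit(med_intercept))


@pytest.fixture(scope="session")
def hunt_config_small():
    return hunt_default_config(n_per_wave=1500, missingness_rate=0.09, seed=0)


@pytest.fixture(scope="session")
def hunt_data_small(hunt_config_small):
    return generate_cohort(hunt_config_small, seed=42)


@pytest.fixture(scope="session")
def linear_config_mid():
    return make_linear_config(5000)


@pytest.fixture(scope="session")
def linear_data_mid(linear_config_mid):
    return generate_cohort(linear_config_mid, seed=7)
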