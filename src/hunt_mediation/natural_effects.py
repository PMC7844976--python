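"""Joint natural effects via imputation-based natural effect models.

The joint natural indirect effect of all mediators together needs no
assumptions about their causal ordering.  It is estimated with the
imputation variant of natural effect models: fit the outcome regression
E[Y | X, M, C] including all exposure x mediator interaction terms, expand
each subject to both hypothetical exposure levels x while keeping the
observed mediator values (drawn under the observed exposure x*), impute the
nested counterfactual Y(x, M(x*)) from the fit, and regress the imputations
on (x, x*, C).  The coefficient on x is the natural direct effect, the
coefficient on x* the natural indirect effect, and with this additive
natural effect model NDE + NIE equals the total effect exactly.

The traditional difference method (exposure coefficient with versus without
the mediators in the regression) is provided for comparison; it coincides
with the natural-effect estimate only in linear no-interaction systems.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import resolve_levels
from .regression import fit_linear, fit_outcome_model
from .specs import MediationResult, MediationSpec
from .splines import rcs_basis

__all__ = ["estimate_joint_nie", "difference_method", "mediated_proportion"]


def _check_binary_exposure(df: pd.DataFrame, spec: MediationSpec) -> None:
    vals = np.unique(df[spec.exposure].to_numpy())
    if not np.array_equal(vals, [0, 1]):
        raise ValueError(
            f"exposure {spec.exposure!r} must be binary 0/1; observed levels {vals}"
        )


def _require_columns(df: pd.DataFrame, spec: MediationSpec) -> None:
    absent = [c for c in spec.model_columns if c not in df.columns]
    if absent:
        raise ValueError(f"columns named in the spec are absent from the data: {absent}")
    incomplete = [
        c for c in spec.model_columns if pd.isna(df[c].to_numpy()).any()
    ]
    if incomplete:
        raise ValueError(
            f"missing values in model columns {incomplete}; apply listwise_delete first"
        )


def estimate_joint_nie(data: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Natural direct/indirect effects of the mediator block (point estimates).

    Standard errors are obtained by passing this estimator to
    :func:`hunt_mediation.sensitivity.bootstrap_ci`.
    """
    df = spec.select_stratum(data)
    _require_columns(df, spec)
    _check_binary_exposure(df, spec)
    spline = rcs_basis(df["age"])
    levels = resolve_levels(df, columns=spec.model_columns)
    outcome_fit = fit_outcome_model(df, spec, spline=spline, levels=levels)

    # expand: one copy per hypothetical direct-exposure level x, keeping the
    # observed mediators (drawn under the observed exposure x*)
    n = len(df)
    nat = pd.concat([df, df], ignore_index=True)
    nat["_x_star"] = np.tile(df[spec.exposure].to_numpy(dtype=float), 2)
    nat[spec.exposure] = np.repeat([0, 1], n)
    nat["_y_imputed"] = outcome_fit.predict(nat)

    ne_terms = ["1", spec.exposure, "_x_star", *spec.covariate_terms]
    ne_fit = fit_linear(nat, "_y_imputed", ne_terms, spline=spline, levels=levels)
    nde = ne_fit.coef(spec.exposure)
    nie = ne_fit.coef("_x_star")
    total = nde + nie
    return MediationResult(
        total_effect=total,
        nde=nde,
        nie=nie,
        mediated_proportion=mediated_proportion(total, nie) if total != 0 else None,
        method="natural_effect_imputation",
        stratum=spec.stratum,
        n_used=len(df),
    )


def difference_method(data: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Traditional mediation estimate: exposure coefficient with vs without mediators.

    Valid only under linearity and no exposure-mediator interaction; reported
    alongside the natural-effect estimate as the historical comparator.
    """
    df = spec.select_stratum(data)
    _require_columns(df, spec)
    _check_binary_exposure(df, spec)
    spline = rcs_basis(df["age"])
    levels = resolve_levels(df)
    terms_without = ["1", spec.exposure, *spec.covariate_terms]
    if spec.intermediate_confounder:
        terms_without.append(f"C({spec.intermediate_confounder})")
    terms_with = terms_without + [f"C({m})" for m in spec.mediators]
    fit_without = fit_linear(df, spec.outcome, terms_without, spline=spline, levels=levels)
    fit_with = fit_linear(df, spec.outcome, terms_with, spline=spline, levels=levels)
    total = fit_without.coef(spec.exposure)
    nde = fit_with.coef(spec.exposure)
    nie = total - nde
    return MediationResult(
        total_effect=total,
        nde=nde,
        nie=nie,
        mediated_proportion=mediated_proportion(total, nie) if total != 0 else None,
        method="difference_method",
        stratum=spec.stratum,
        n_used=len(df),
    )


def mediated_proportion(total: float, nie: float) -> float:
    """NIE as a fraction of the total effect (unitless).

    Undefined at a null total effect; reporting layers round to two decimals
    in tables and to the nearest percent in summaries.
    """
    if total == 0:
        raise ValueError("mediated proportion is undefined when the total effect is 0")
    return nie / total
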