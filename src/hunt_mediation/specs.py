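"""Declarative description of one mediation analysis.

A :class:`MediationSpec` names the causal roles — exposure (study wave),
outcome (one hearing-threshold band), the mediator set, an optional
exposure-induced intermediate confounder, and the stratum — and carries the
modelling flags (exposure x mediator interactions, identification strategy)
that the estimators consume.  :class:`MediationResult` is the common result
record all estimators return.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Union

import pandas as pd

from .datasets import CATEGORY_LEVELS, OUTCOME_COLUMNS

__all__ = ["MediationSpec", "MediationResult", "IDENTIFICATIONS", "STRATA"]

IDENTIFICATIONS = ("none_required", "no_XM_interaction", "linear_L_effect")
STRATA = ("all", "women", "men")
_MEDIATOR_CHOICES = ("education", "ear_infections", "noise", "smoking")


@dataclass(frozen=True)
class MediationSpec:
    """Roles and assumptions for one mediation contrast.

    Parameters
    ----------
    outcome
        ``"ht_low"`` or ``"ht_high"``.
    mediators
        Ordered subset of ``{education, ear_infections, noise, smoking}``.
        The joint estimators treat these as one block; the g-formula
        estimators take a single focal mediator.
    intermediate_confounder
        Optional exposure-induced mediator-outcome confounder (education,
        when it is not itself the mediator of interest).
    interactions
        Whether exposure x mediator product terms enter the outcome model.
    identification
        Extra assumption used by the g-formula when an intermediate
        confounder is present: ``no_XM_interaction`` (no exposure-mediator
        interaction) or ``linear_L_effect`` (confounder enters the outcome
        linearly, with no exposure-confounder interaction).
    stratum
        ``all`` (sex enters as a covariate) or ``women`` / ``men``
        (sex filters the rows and leaves the model).
    """

    outcome: str
    mediators: tuple[str, ...]
    exposure: str = "wave"
    intermediate_confounder: Optional[str] = None
    interactions: bool = True
    identification: str = "none_required"
    stratum: str = "all"

    def __post_init__(self):
        object.__setattr__(self, "mediators", tuple(self.mediators))
        if self.outcome not in OUTCOME_COLUMNS:
            raise ValueError(f"outcome must be one of {OUTCOME_COLUMNS}")
        if not self.mediators:
            raise ValueError("mediators must be non-empty")
        bad = [m for m in self.mediators if m not in _MEDIATOR_CHOICES]
        if bad:
            raise ValueError(f"unknown mediators {bad}; choose from {_MEDIATOR_CHOICES}")
        if len(set(self.mediators)) != len(self.mediators):
            raise ValueError("mediators must be distinct")
        if self.intermediate_confounder is not None:
            if self.intermediate_confounder in self.mediators:
                raise ValueError("intermediate confounder cannot also be a mediator")
            if self.intermediate_confounder not in CATEGORY_LEVELS:
                raise ValueError(
                    f"unknown intermediate confounder {self.intermediate_confounder!r}"
                )
        if self.identification not in IDENTIFICATIONS:
            raise ValueError(f"identification must be one of {IDENTIFICATIONS}")
        if self.stratum not in STRATA:
            raise ValueError(f"stratum must be one of {STRATA}")
        roles = [self.exposure, self.outcome, *self.mediators]
        if self.intermediate_confounder:
            roles.append(self.intermediate_confounder)
        if len(set(roles)) != len(roles):
            raise ValueError("exposure, outcome, mediators and confounder must be distinct")

    @property
    def covariate_terms(self) -> list[str]:
        """Baseline covariate terms: spline(age) always, sex only when pooled."""
        terms = ["rcs(age)"]
        if self.stratum == "all":
            terms.append("sex")
        return terms

    def select_stratum(self, df: pd.DataFrame) -> pd.DataFrame:
        if self.stratum == "all":
            return df
        code = 0 if self.stratum == "women" else 1
        out = df[df["sex"] == code]
        if len(out) == 0:
            raise ValueError(f"stratum {self.stratum!r} selects no rows")
        return out

    @property
    def model_columns(self) -> list[str]:
        cols = [self.exposure, self.outcome, "age", "sex", *self.mediators]
        if self.intermediate_confounder:
            cols.append(self.intermediate_confounder)
        return cols


@dataclass
class MediationResult:
    """Point estimates (dB scale) with optional bootstrap uncertainty.

    ``nie`` is a float for single-path estimators and a ``{mediator: dB}``
    map when several specific effects are reported together.  ``se`` and
    ``ci`` are keyed by quantity name (``"total"``, ``"nde"``, ``"nie"``).
    """

    total_effect: float
    nde: float
    nie: Union[float, dict]
    mediated_proportion: Optional[float]
    method: str
    stratum: str
    n_used: int
    n_dropped_missing: int = 0
    se: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)
    mc_error: Optional[float] = None
    notes: tuple[str, ...] = ()

    def __post_init__(self):
        for key, (lo, hi) in self.ci.items():
            point = getattr(self, key if key != "total" else "total_effect", None)
            if isinstance(point, (int, float)) and not (lo - 1e-12 <= point <= hi + 1e-12):
                raise ValueError(f"CI for {key!r} does not bracket the point estimate")

    def to_dict(self) -> dict:
        return asdict(self)
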