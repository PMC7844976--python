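"""Component regressions behind every estimator.

Two model families are needed: Gaussian linear models for the hearing
thresholds (ordinary least squares, restricted-cubic-spline age adjustment,
optional exposure interactions) and baseline-category multinomial logits for
the categorical mediators and the intermediate confounder.  Both are fit with
statsmodels; this module owns design construction, rank diagnostics, the
common :class:`FittedModel` record, Wald joint tests, and the spline-versus-
linear-age likelihood-ratio comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .datasets import CATEGORY_LEVELS
from .design import build_design, resolve_levels
from .specs import MediationSpec
from .splines import SplineBasis, rcs_basis

__all__ = [
    "FittedModel",
    "fit_linear",
    "fit_outcome_model",
    "fit_categorical_model",
    "lrt_spline_vs_linear",
    "wald_joint_test",
    "outcome_terms",
]


@dataclass
class FittedModel:
    """A fitted component model with enough state to predict on new data.

    ``cov`` (covariance of the flattened parameters) is computed lazily for
    multinomial fits — simulation and bootstrap loops never touch it.
    """

    family: str                      # "gaussian" | "multinomial"
    target: str
    terms: list[str]
    names: list[str]                 # design column names
    params: np.ndarray               # (p,) gaussian; (p, J-1) multinomial
    loglik: float
    nobs: int
    spline: Optional[SplineBasis]
    levels: dict = field(default_factory=dict)
    resid_sd: Optional[float] = None  # gaussian only (ML scale)
    target_levels: Optional[list] = None  # multinomial only
    _cov: Optional[np.ndarray] = None
    _cov_builder: Optional[callable] = None

    @property
    def cov(self) -> np.ndarray:
        if self._cov is None:
            self._cov = self._cov_builder()
        return self._cov

    def design(self, df: pd.DataFrame) -> np.ndarray:
        X, _ = build_design(df, self.terms, spline=self.spline, levels=self.levels)
        return X

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Conditional mean (gaussian family)."""
        if self.family != "gaussian":
            raise ValueError("predict() is for the gaussian family")
        return self.design(df) @ self.params

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        """Per-subject class probabilities, shape (n, J) (multinomial family)."""
        if self.family != "multinomial":
            raise ValueError("predict_proba() is for the multinomial family")
        return _softmax_ref(self.design(df) @ self.params)

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def linear_predictor(self, varmap: dict, n: int) -> np.ndarray:
        """Evaluate the linear predictor(s) from structured inputs.

        ``varmap`` supplies per-subject arrays (or scalars) keyed by column
        name, with ``"age_basis"`` holding a precomputed spline basis and
        categorical columns given as level codes.  This bypasses data-frame
        design construction for simulation loops; it returns ``(n,)`` for
        gaussian fits and ``(n, J-1)`` for multinomial fits.
        """
        params = self.params if self.params.ndim == 2 else self.params[:, None]
        out = np.zeros((n, params.shape[1]))
        for name, row in zip(self.names, params):
            v = _eval_column(name, varmap, self.levels, n)
            if np.ndim(v) == 0:
                out += float(v) * row
            else:
                out += np.multiply.outer(np.asarray(v, dtype=float), row)
        return out if self.family == "multinomial" else out[:, 0]

    def proba_from(self, varmap: dict, n: int) -> np.ndarray:
        """Class probabilities from structured inputs (multinomial family)."""
        return _softmax_ref(self.linear_predictor(varmap, n))

    def to_json_dict(self) -> dict:
        flat = np.asarray(self.params, dtype=float)
        se = np.sqrt(np.clip(np.diag(self.cov), 0.0, None))
        return {
            "family": self.family,
            "target": self.target,
            "terms": list(self.terms),
            "names": list(self.names),
            "params": flat.tolist(),
            "se": se.tolist(),
            "loglik": self.loglik,
            "nobs": self.nobs,
        }


def _eval_column(name: str, varmap: dict, levels: dict, n: int):
    """Value of one design column from structured inputs (see linear_predictor)."""
    if ":" in name:
        parts = name.split(":")
        v = _eval_column(parts[0], varmap, levels, n)
        for part in parts[1:]:
            v = np.asarray(v, dtype=float) * np.asarray(
                _eval_column(part, varmap, levels, n), dtype=float
            )
        return v
    if name == "Intercept":
        return 1.0
    if name == "age":
        return varmap["age_basis"][:, 0]
    if name.startswith("rcs(age)["):
        return varmap["age_basis"][:, int(name[9:-1])]
    if name.startswith("C(") and name.endswith("]"):
        col, lvl = name[2:-1].split(")[")
        return (np.asarray(varmap[col]) == int(lvl)).astype(float)
    if name.startswith("score(") and name.endswith(")"):
        col = name[6:-1]
        return np.asarray(varmap[col], dtype=float) - levels[col][0]
    return varmap[name]


def _softmax_ref(eta: np.ndarray) -> np.ndarray:
    """Softmax over [0 | eta] — reference category has linear predictor 0."""
    full = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=1, keepdims=True)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # greedy scan: report columns that are linear combinations of predecessors
    culprits = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        cols = kept + [j]
        if np.linalg.matrix_rank(X[:, cols]) == len(cols):
            kept.append(j)
        else:
            culprits.append(names[j])
    raise ValueError(f"rank-deficient design; collinear terms: {culprits}")


def fit_linear(
    df: pd.DataFrame,
    outcome: str,
    terms: list[str],
    spline: SplineBasis | None = None,
    levels: dict | None = None,
) -> FittedModel:
    """Ordinary least squares of ``outcome`` on the expanded ``terms``."""
    if levels is None:
        levels = resolve_levels(df)
    y = df[outcome].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"outcome {outcome!r} has non-finite values")
    X, names = build_design(df, terms, spline=spline, levels=levels)
    res = sm.OLS(y, X).fit()
    if res.model.rank < X.shape[1]:
        _check_rank(X, names)  # raises naming the collinear terms
    resid_sd = float(np.sqrt(res.ssr / res.nobs))  # ML scale, consistent with llf
    return FittedModel(
        family="gaussian",
        target=outcome,
        terms=list(terms),
        names=names,
        params=np.asarray(res.params, dtype=float),
        loglik=float(res.llf),
        nobs=int(res.nobs),
        spline=spline,
        levels=dict(levels),
        resid_sd=resid_sd,
        _cov=np.asarray(res.cov_params(), dtype=float),
    )


def outcome_terms(spec: MediationSpec, interactions: tuple[str, ...] | None = None) -> list[str]:
    """Standard outcome-model term list for a spec.

    Includes intercept, exposure, baseline covariates, dummy-coded mediators
    (and intermediate confounder when present), plus any explicitly requested
    interaction terms; when ``interactions`` is None and
    ``spec.interactions`` is set, all exposure x mediator products are added.
    """
    terms = ["1", spec.exposure, *spec.covariate_terms]
    if spec.intermediate_confounder:
        terms.append(f"C({spec.intermediate_confounder})")
    terms += [f"C({m})" for m in spec.mediators]
    if interactions is None:
        interactions = (
            tuple(f"{spec.exposure}:C({m})" for m in spec.mediators)
            if spec.interactions
            else ()
        )
    terms += list(interactions)
    return terms


def fit_outcome_model(
    data: pd.DataFrame,
    spec: MediationSpec,
    interactions: tuple[str, ...] | None = None,
    spline: SplineBasis | None = None,
    levels: dict | None = None,
) -> FittedModel:
    """Fit the linear outcome model the spec describes, on the spec's stratum.

    Rows must be complete on the model columns (apply
    :func:`hunt_mediation.pipeline.listwise_delete` first).
    """
    df = spec.select_stratum(data)
    if spline is None:
        spline = rcs_basis(df["age"])
    return fit_linear(
        df, spec.outcome, outcome_terms(spec, interactions), spline=spline, levels=levels
    )


def fit_categorical_model(
    data: pd.DataFrame,
    target: str,
    terms: list[str],
    spline: SplineBasis | None = None,
    levels: dict | None = None,
    maxiter: int = 200,
) -> FittedModel:
    """Baseline-category multinomial logit of ``target`` on ``terms``.

    The reference category is the first declared level.  Raises on
    non-convergence or on quasi-separation (runaway coefficients), advising
    category collapse in the latter case.
    """
    if levels is None:
        levels = resolve_levels(data)
    vals = data[target].to_numpy()
    if pd.isna(vals).any():
        raise ValueError(f"target {target!r} has missing values; apply listwise_delete first")
    observed = np.unique(vals)
    if observed.size < 2:
        raise ValueError(f"target {target!r} has fewer than 2 observed levels")
    declared = CATEGORY_LEVELS.get(target, sorted(observed.tolist()))
    target_levels = [l for l in declared if l in set(observed.tolist())]
    if len(target_levels) != observed.size:
        raise ValueError(f"target {target!r} has codes outside its declared levels")
    codes = np.searchsorted(np.asarray(target_levels), vals.astype(int))
    X, names = build_design(data, terms, spline=spline, levels=levels)
    # QR-precondition the design: Newton then converges in a handful of
    # iterations regardless of column scaling or collinearity of the spline
    # columns, and R's diagonal doubles as the rank diagnostic
    Q, Rmat = np.linalg.qr(X)
    diag = np.abs(np.diag(Rmat))
    if diag.min() < 1e-10 * max(diag.max(), 1.0):
        _check_rank(X, names)  # raises with the collinear term names
    try:
        gamma, loglik, converged = _newton_multinomial(
            Q, codes, len(target_levels), maxiter=maxiter
        )
    except np.linalg.LinAlgError as err:  # pragma: no cover - degenerate hessian
        raise ValueError(
            f"multinomial fit for {target!r} failed ({err}); a category may be "
            "empty or separated — consider collapsing sparse levels"
        ) from err
    if not converged:
        raise ValueError(
            f"multinomial fit for {target!r} did not converge after {maxiter} "
            "iterations"
        )
    params = np.linalg.solve(Rmat, gamma)  # undo preconditioning: (p, J-1)
    eta = X @ params
    # near-separation pins probabilities at 0/1 but the fit stays usable for
    # prediction and simulation; reject only numerically degenerate results
    if not np.all(np.isfinite(eta)) or np.abs(eta).max() > 1e4:
        raise ValueError(
            f"multinomial fit for {target!r} is degenerate (separation); "
            "collapse sparse categories and refit"
        )
    probs = _softmax_ref(eta)
    return FittedModel(
        family="multinomial",
        target=target,
        terms=list(terms),
        names=names,
        params=params,
        loglik=loglik,
        nobs=int(len(codes)),
        spline=spline,
        levels=dict(levels),
        target_levels=list(target_levels),
        _cov_builder=lambda: _multinomial_cov(X, probs),
    )


def _newton_multinomial(
    Q: np.ndarray, codes: np.ndarray, n_levels: int, maxiter: int, tol: float = 1e-8
) -> tuple[np.ndarray, float, bool]:
    """Newton-Raphson fit of a reference-coded multinomial logit.

    ``Q`` must have orthonormal columns (QR-preconditioned design); the
    convergence criterion is a relative log-likelihood change below ``tol``,
    with step halving whenever a full Newton step would decrease the
    likelihood.  Returns the coefficients in the preconditioned basis.
    """
    n, p = Q.shape
    jm1 = n_levels - 1
    Yind = np.zeros((n, jm1))
    for j in range(jm1):
        Yind[:, j] = codes == j + 1
    gamma = np.zeros((p, jm1))
    rows = np.arange(n)

    def loglik_of(g):
        probs = _softmax_ref(Q @ g)
        return float(np.log(probs[rows, codes] + 1e-300).sum()), probs

    ll, probs = loglik_of(gamma)
    converged = False
    H = np.empty((p * jm1, p * jm1))
    for _ in range(maxiter):
        p_non = probs[:, 1:]
        grad = Q.T @ (Yind - p_non)                    # (p, J-1)
        # Fisher information in p x p blocks: H_jk = Q' diag(d_jk p_j - p_j p_k) Q
        for j in range(jm1):
            for k in range(j, jm1):
                w = p_non[:, j] * ((1.0 if j == k else 0.0) - p_non[:, k])
                block = Q.T @ (Q * w[:, None])
                H[j * p:(j + 1) * p, k * p:(k + 1) * p] = block
                if k != j:
                    H[k * p:(k + 1) * p, j * p:(j + 1) * p] = block.T
        H[np.diag_indices_from(H)] += 1e-10
        step = np.linalg.solve(H, grad.ravel(order="F")).reshape(jm1, p).T
        scale = 1.0
        for _halve in range(30):
            ll_new, probs_new = loglik_of(gamma + scale * step)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        gamma = gamma + scale * step
        improved = ll_new - ll
        ll, probs = ll_new, probs_new
        if abs(improved) <= tol * (abs(ll) + 1.0):
            converged = True
            break
    return gamma, ll, converged


def _multinomial_cov(X: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Inverse observed information for reference-coded multinomial params.

    Parameter order matches ``params.ravel(order="F")`` — all design
    coefficients for category 2, then category 3, and so on.
    """
    p_non = probs[:, 1:]                       # (n, J-1)
    W = -np.einsum("ij,ik->ijk", p_non, p_non)  # -p_j p_k
    jj = np.arange(p_non.shape[1])
    W[:, jj, jj] += p_non
    info = np.einsum("ijk,ia,ib->jakb", W, X, X, optimize=True)
    k = p_non.shape[1] * X.shape[1]
    info = info.reshape(k, k)
    try:
        return np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(info)


def lrt_spline_vs_linear(
    data: pd.DataFrame, spec: MediationSpec
) -> tuple[float, int, float]:
    """Likelihood-ratio test of 5-knot spline age versus linear age.

    Both outcome models are fit on exactly the stratum rows of ``data``
    (which must be complete); the statistic is ``2 (ll_spline − ll_linear)``
    with df = number of nonlinear spline columns (3 for five knots).
    """
    df = spec.select_stratum(data)
    spline = rcs_basis(df["age"])
    terms_spline = outcome_terms(spec)
    terms_linear = [t if t != "rcs(age)" else "age" for t in terms_spline]
    fit_s = fit_linear(df, spec.outcome, terms_spline, spline=spline)
    fit_l = fit_linear(df, spec.outcome, terms_linear, spline=spline)
    if fit_s.nobs != fit_l.nobs:
        raise ValueError("nested models were fit on different row sets")
    stat = max(0.0, 2.0 * (fit_s.loglik - fit_l.loglik))
    dof = spline.basis_dim - 1
    p = float(scipy.stats.chi2.sf(stat, dof))
    return stat, dof, p


def wald_joint_test(fit: FittedModel, names: list[str]) -> tuple[float, int, float]:
    """Joint Wald chi-square test that the named coefficients are all zero."""
    if fit.family != "gaussian":
        raise ValueError("wald_joint_test expects a gaussian fit")
    idx = [fit.names.index(n) for n in names]
    theta = fit.params[idx]
    V = fit.cov[np.ix_(idx, idx)]
    stat = float(theta @ np.linalg.solve(V, theta))
    dof = len(idx)
    return stat, dof, float(scipy.stats.chi2.sf(stat, dof))
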