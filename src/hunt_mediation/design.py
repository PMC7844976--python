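"""Design-matrix construction from a compact term language.

Model formulas in this package are lists of term strings:

``"1"``
    intercept;
``"wave"``
    a numeric column taken as-is;
``"C(noise)"``
    treatment (dummy) coding of a categorical column against its *declared*
    level set, reference = first level;
``"score(education)"``
    the ordinal score of a categorical column (level code minus the first
    declared level), as a single numeric column;
``"rcs(age)"``
    the restricted-cubic-spline expansion of age for a supplied
    :class:`~hunt_mediation.splines.SplineBasis`;
``"wave:C(noise)"``
    interaction — the elementwise product of the two expansions.

Dummy coding always uses the declared levels (see
:data:`hunt_mediation.datasets.CATEGORY_LEVELS`), not the levels observed in
the particular data frame, so coefficient vectors remain conformable across
bootstrap resamples and strata.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import CATEGORY_LEVELS
from .splines import SplineBasis

__all__ = ["build_design", "resolve_levels"]


def resolve_levels(
    df: pd.DataFrame,
    levels: dict[str, list] | None = None,
    columns: list[str] | None = None,
) -> dict[str, list]:
    """Effective level sets for this table: declared levels actually observed.

    Fitting against the observed subset keeps designs full-rank when a
    configuration uses fewer levels than the schema declares; the resolved
    dict is stored on the fitted model so prediction on new frames uses the
    same coding.  ``columns`` restricts the scan (other columns keep their
    declared levels).
    """
    if levels is None:
        levels = CATEGORY_LEVELS
    out = {}
    for col, declared in levels.items():
        if columns is not None and col not in columns:
            out[col] = declared
            continue
        if col in df.columns:
            vals = df[col].to_numpy(dtype=float, na_value=np.nan)
            present = np.unique(vals[~np.isnan(vals)])
            observed = [l for l in declared if l in present]
            out[col] = observed if len(observed) >= 2 else declared
        else:
            out[col] = declared
    return out


def _expand_atom(
    df: pd.DataFrame,
    atom: str,
    spline: SplineBasis | None,
    levels: dict[str, list],
) -> tuple[np.ndarray, list[str]]:
    if atom == "1":
        return np.ones((len(df), 1)), ["Intercept"]
    if atom.startswith("rcs(") and atom.endswith(")"):
        col = atom[4:-1]
        if spline is None:
            raise ValueError(f"term {atom!r} requires a SplineBasis")
        mat = spline.transform(df[col].to_numpy(dtype=float))
        names = [col] + [f"rcs({col})[{i + 1}]" for i in range(mat.shape[1] - 1)]
        return mat, names
    if atom.startswith("C(") and atom.endswith(")"):
        col = atom[2:-1]
        lv = levels.get(col)
        if lv is None:
            raise ValueError(f"no declared levels for categorical column {col!r}")
        vals = df[col].to_numpy()
        cols = [(vals == level).astype(float) for level in lv[1:]]
        names = [f"C({col})[{level}]" for level in lv[1:]]
        return np.column_stack(cols), names
    if atom.startswith("score(") and atom.endswith(")"):
        col = atom[6:-1]
        lv = levels.get(col)
        base = lv[0] if lv else 0
        return (df[col].to_numpy(dtype=float) - base)[:, None], [f"score({col})"]
    if atom not in df.columns:
        raise ValueError(f"unknown model term {atom!r}")
    return df[atom].to_numpy(dtype=float)[:, None], [atom]


def build_design(
    df: pd.DataFrame,
    terms: list[str],
    spline: SplineBasis | None = None,
    levels: dict[str, list] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Build an ``(n, p)`` design matrix and its column names.

    Interactions (``a:b``) expand to all pairwise column products of the
    factor expansions.  Raises ``ValueError`` for unknown columns or missing
    level declarations; non-finite values in numeric columns raise as well,
    because every estimator in this package requires complete data (apply
    :func:`hunt_mediation.pipeline.listwise_delete` first).
    """
    if levels is None:
        levels = CATEGORY_LEVELS
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for term in terms:
        atoms = term.split(":")
        mat, nm = _expand_atom(df, atoms[0], spline, levels)
        for atom in atoms[1:]:
            m2, n2 = _expand_atom(df, atom, spline, levels)
            mat = np.einsum("ni,nj->nij", mat, m2).reshape(len(df), -1)
            nm = [f"{a}:{b}" for a in nm for b in n2]
        blocks.append(mat)
        names.extend(nm)
    X = np.hstack(blocks) if blocks else np.empty((len(df), 0))
    if not np.all(np.isfinite(X)):
        bad = [names[j] for j in np.where(~np.isfinite(X).all(axis=0))[0]]
        raise ValueError(f"non-finite values in design columns: {bad}")
    return X, names
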