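"""Cohort table schema, validation and delimited-text IO.

The unit of analysis is one subject from one of two cross-sectional study
waves.  The canonical in-memory container is a plain :class:`pandas.DataFrame`
with the columns below; :func:`validate_cohort` enforces the schema and
``read_cohort`` / ``write_cohort`` move it to and from UTF-8 CSV with a
sidecar JSON codebook recording category labels and codes.

Columns
-------
subject_id : str
wave : int, 0 = earlier wave (HUNT2, reference), 1 = later wave (HUNT4)
age : float, years, within [20, 101]
sex : int, 0 = woman, 1 = man
education : int 1-4 (primary / secondary / university < 4 y / university >= 4 y)
noise : int 1-4, weekly occupational noise (never / < 5 h / 5-15 h / > 15 h);
    may be missing (NaN)
ear_infections : int 1-3 (no / maybe / yes); may be missing
smoking : int 1-3, daily smoking (never / former / current); may be missing
ht_low : float, hearing threshold in dB averaged over both ears at
    0.5, 1 and 2 kHz
ht_high : float, dB averaged over both ears at 3, 4 and 6 kHz
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORY_LEVELS",
    "CATEGORY_LABELS",
    "MEDIATOR_COLUMNS",
    "OUTCOME_COLUMNS",
    "validate_cohort",
    "read_cohort",
    "write_cohort",
    "average_ht",
]

#: Declared level codes per categorical column (first level = reference).
CATEGORY_LEVELS: dict[str, list] = {
    "wave": [0, 1],
    "sex": [0, 1],
    "education": [1, 2, 3, 4],
    "noise": [1, 2, 3, 4],
    "ear_infections": [1, 2, 3],
    "smoking": [1, 2, 3],
}

#: Human-readable labels, written to the sidecar codebook.
CATEGORY_LABELS: dict[str, dict] = {
    "wave": {0: "HUNT2 (1996-1998)", 1: "HUNT4 (2017-2019)"},
    "sex": {0: "woman", 1: "man"},
    "education": {
        1: "primary school",
        2: "secondary school",
        3: "university < 4 years",
        4: "university >= 4 years",
    },
    "noise": {1: "never", 2: "< 5 h/week", 3: "5-15 h/week", 4: "> 15 h/week"},
    "ear_infections": {1: "no", 2: "maybe", 3: "yes"},
    "smoking": {1: "never", 2: "former", 3: "current"},
}

MEDIATOR_COLUMNS = ("noise", "ear_infections", "smoking")
OUTCOME_COLUMNS = ("ht_low", "ht_high")

_LOW_FREQS = (0.5, 1.0, 2.0)
_HIGH_FREQS = (3.0, 4.0, 6.0)


def validate_cohort(df: pd.DataFrame, require_complete: bool = False) -> pd.DataFrame:
    """Check a cohort table against the schema; returns the frame unchanged.

    Mediator columns may contain NaN unless ``require_complete``; all other
    schema violations raise ``ValueError`` naming the offending column.
    """
    required = ["subject_id", "wave", "age", "sex", "education",
                "noise", "ear_infections", "smoking", "ht_low", "ht_high"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    for col in ("wave", "sex", "education"):
        vals = df[col].to_numpy()
        if not np.isin(vals, CATEGORY_LEVELS[col]).all():
            raise ValueError(f"column {col!r} has codes outside {CATEGORY_LEVELS[col]}")
    for col in MEDIATOR_COLUMNS:
        vals = df[col].to_numpy(dtype=float)
        obs = vals[~np.isnan(vals)]
        if require_complete and len(obs) < len(vals):
            raise ValueError(f"mediator column {col!r} has missing values")
        if not np.isin(obs, CATEGORY_LEVELS[col]).all():
            raise ValueError(f"column {col!r} has codes outside {CATEGORY_LEVELS[col]}")
    for col in OUTCOME_COLUMNS:
        if not np.isfinite(df[col].to_numpy(dtype=float)).all():
            raise ValueError(f"outcome column {col!r} must be finite for all rows")
    age = df["age"].to_numpy(dtype=float)
    if not ((age >= 20.0) & (age <= 101.0)).all():
        raise ValueError("age must lie within [20, 101]")
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as UTF-8 CSV plus a ``<path>.schema.json`` codebook."""
    path = Path(path)
    validate_cohort(df)
    df.to_csv(path, index=False, encoding="utf-8")
    codebook = {
        "columns": list(df.columns),
        "category_levels": CATEGORY_LEVELS,
        "category_labels": {
            c: {str(k): v for k, v in lab.items()} for c, lab in CATEGORY_LABELS.items()
        },
        "outcome_units": "dB hearing threshold (negative change = improvement)",
    }
    path.with_suffix(path.suffix + ".schema.json").write_text(
        json.dumps(codebook, indent=2), encoding="utf-8"
    )


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort` (or of the same schema)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    for col in ("wave", "sex", "education"):
        df[col] = df[col].astype(int)
    return validate_cohort(df)


def average_ht(thresholds: dict) -> tuple[float, float]:
    """Average per-ear pure-tone thresholds into the two outcome bands.

    Parameters
    ----------
    thresholds
        Nested mapping ``{ear: {frequency_kHz: dB}}`` with ears ``"left"``
        and ``"right"`` and frequencies 0.5, 1, 2 (low band) and 3, 4, 6
        (high band).

    Returns
    -------
    (ht_low, ht_high)
        Means over the six values (2 ears x 3 frequencies) per band.
    """
    missing = []
    for ear in ("left", "right"):
        per_ear = thresholds.get(ear, {})
        for f in _LOW_FREQS + _HIGH_FREQS:
            if f not in per_ear or not np.isfinite(per_ear[f]):
                missing.append((ear, f))
    if missing:
        raise ValueError(f"missing or non-finite threshold cells: {missing}")
    low = np.mean([thresholds[e][f] for e in ("left", "right") for f in _LOW_FREQS])
    high = np.mean([thresholds[e][f] for e in ("left", "right") for f in _HIGH_FREQS])
    return float(low), float(high)
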