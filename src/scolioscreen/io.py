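"""Cohort CSV interchange: fixed header, validated levels, lossless round-trip.

The interchange format is UTF-8 comma-delimited CSV with exactly the
record columns (gender, age, school, the nine postural signs, ais) and
the canonical lower-case level strings.  Reading is strict: missing
columns, unknown levels, non-numeric ages and duplicate headers are
errors carrying row numbers; differently-cased level strings are
normalized with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .variables import RECORD_COLUMNS, VARIABLES

__all__ = ["write_cohort", "read_cohort", "CohortFormatError"]


class CohortFormatError(ValueError):
    """A cohort CSV violates the documented format."""


def write_cohort(records: pd.DataFrame, path) -> None:
    """Write a cohort frame with the fixed header; ages at full precision."""
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise CohortFormatError(f"cohort frame missing columns: {sorted(missing)}")
    records[list(RECORD_COLUMNS)].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort`.

    Level strings are case-normalized (with a warning when any change);
    every validation error reports the offending data row numbers
    (1-based, excluding the header).
    """
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise CohortFormatError(f"{path}: empty file, not an empty cohort")
    header = [h.strip() for h in header_line.rstrip("\n").split(",")]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise CohortFormatError(f"{path}: duplicate header column(s) {dupes}")
    missing = [c for c in RECORD_COLUMNS if c not in header]
    if missing:
        raise CohortFormatError(f"{path}: missing column(s) {missing}")

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df[list(RECORD_COLUMNS)]

    # age
    age = pd.to_numeric(df["age"], errors="coerce")
    bad = np.flatnonzero(age.isna().to_numpy())
    if bad.size:
        raise CohortFormatError(
            f"{path}: non-numeric age at row(s) {(bad + 1).tolist()[:10]}"
        )
    df["age"] = age.astype(float)

    # ais label
    if not df["ais"].isin(("0", "1")).all():
        bad = np.flatnonzero(~df["ais"].isin(("0", "1")).to_numpy())
        raise CohortFormatError(
            f"{path}: ais must be 0 or 1; bad row(s) {(bad + 1).tolist()[:10]}"
        )
    df["ais"] = df["ais"].astype(np.int64)

    normalized = False
    for name, vdef in VARIABLES.items():
        col = df[name]
        lowered = col.str.strip().str.lower()
        if not lowered.equals(col):
            normalized = True
        unknown = ~lowered.isin(vdef.levels)
        if unknown.any():
            rows = (np.flatnonzero(unknown.to_numpy()) + 1).tolist()[:10]
            values = sorted(lowered[unknown].unique())
            raise CohortFormatError(
                f"{path}: unknown {name} level(s) {values} at row(s) {rows}"
            )
        df[name] = lowered
    if normalized:
        warnings.warn(
            f"{path}: level strings were case/whitespace-normalized",
            UserWarning,
            stacklevel=2,
        )
    return df
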