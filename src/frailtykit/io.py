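"""Cohort table IO: delimited text with header, column mapping, validation.

A cohort file is a CSV whose columns carry the deficit items (named by
schema item id, or bound via a ``column_map``), covariates, follow-up
time and event indicator. Rows failing type or range validation are
quarantined with their line numbers and reported, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortReadResult", "read_cohort", "write_cohort"]

REQUIRED_COLUMNS = ("follow_up_time", "event")


@dataclass
class CohortReadResult:
    """Validated cohort plus the row-level rejection report."""

    data: pd.DataFrame
    n_read: int
    rejected: list[dict] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def read_cohort(
    path,
    column_map: dict[str, str] | None = None,
    item_ids: list[str] | None = None,
    min_age: float | None = 60.0,
) -> CohortReadResult:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path : str or file-like
        Delimited text with a header row.
    column_map : dict, optional
        Maps canonical names (``age``, ``event``, item ids, ...) to the
        file's column names, so arbitrary survey exports can be bound.
    item_ids : list of str, optional
        Deficit-item columns that must be present after mapping.
    min_age : float, optional
        Cohort inclusion threshold; rows below it are quarantined.
        ``None`` disables the age screen.

    Raises
    ------
    ValueError
        If a mapped or required column is missing entirely (fatal, names
        the column). Cell-level problems quarantine the row instead.
    """
    raw = pd.read_csv(path)
    if column_map:
        missing_src = [src for src in column_map.values() if src not in raw.columns]
        if missing_src:
            raise ValueError(f"mapped column(s) not in file: {missing_src}")
        raw = raw.rename(columns={v: k for k, v in column_map.items()})
    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"required column {col!r} missing from cohort file")
    for col in item_ids or []:
        if col not in raw.columns:
            raise ValueError(f"deficit item column {col!r} missing from cohort file")

    rejected: list[dict] = []
    keep = np.ones(len(raw), dtype=bool)

    def _numeric(col: str, reason: str):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna()
        for i in raw.index[bad]:
            rejected.append({"line": int(i) + 2, "column": col, "reason": reason})
        keep[np.asarray(bad)] = False
        return vals

    time = _numeric("follow_up_time", "unparsable follow-up time")
    event = _numeric("event", "unparsable event indicator")
    bad_time = time.notna() & (time <= 0)
    for i in raw.index[bad_time]:
        rejected.append({"line": int(i) + 2, "column": "follow_up_time",
                         "reason": "non-positive follow-up time"})
    keep &= ~np.asarray(bad_time)
    bad_event = event.notna() & ~event.isin((0, 1))
    for i in raw.index[bad_event]:
        rejected.append({"line": int(i) + 2, "column": "event",
                         "reason": "event must be 0 or 1"})
    keep &= ~np.asarray(bad_event)
    if "age" in raw.columns:
        age = _numeric("age", "unparsable age")
        if min_age is not None:
            bad_age = age.notna() & (age < min_age)
            for i in raw.index[bad_age]:
                rejected.append({"line": int(i) + 2, "column": "age",
                                 "reason": f"age below cohort minimum {min_age}"})
            keep &= ~np.asarray(bad_age)

    data = raw.loc[keep].copy()
    for col in ("follow_up_time", "age"):
        if col in data.columns:
            data[col] = pd.to_numeric(data[col])
    if "event" in data.columns:
        data["event"] = pd.to_numeric(data["event"]).astype(int)
    data = data.reset_index(drop=True)
    return CohortReadResult(data=data, n_read=len(raw), rejected=rejected)


def write_cohort(data: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV (round-trips with :func:`read_cohort`)."""
    data.to_csv(path, index=False)
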