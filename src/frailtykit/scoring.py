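"""Frailty-index computation and severity classification.

The frailty index (FI) of a subject is the number of deficits present
divided by the number of items considered. With a complete 30-item record
this is ``count / 30``; under item missingness the denominator policy is
configurable ("fixed" keeps the full catalogue size, "observed" — the
standard deficit-accumulation practice — divides by the number of items
actually observed, gated by the schema's ``min_observed_fraction``).

Severity categories are assigned from a :class:`~frailtykit.sslr.CutpointSet`
with right-closed intervals: the lowest category is ``[0, c1]``, subsequent
ones ``(c_k, c_{k+1}]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .schema import MISSING, DeficitSchema

__all__ = [
    "FrailtyScore",
    "FrailtyUndefinedError",
    "compute_frailty_index",
    "classify_frailty",
    "score_cohort",
]

DenominatorPolicy = Literal["fixed", "observed"]


class FrailtyUndefinedError(ValueError):
    """Too many missing items to compute a frailty index for a subject."""


@dataclass(frozen=True)
class FrailtyScore:
    """Frailty index for one subject."""

    fi: float
    n_deficits: int
    n_observed: int
    category: str | None = None


def compute_frailty_index(
    deficits: Sequence[int],
    schema: DeficitSchema,
    denominator: DenominatorPolicy = "observed",
) -> FrailtyScore:
    """Compute the frailty index from a coded deficit vector.

    Parameters
    ----------
    deficits : sequence of {0, 1, MISSING}
        Coded deficit values aligned to ``schema.items``.
    schema : DeficitSchema
        Supplies the catalogue size and the missingness gate.
    denominator : {"observed", "fixed"}
        "observed" divides by the number of non-missing items (subject to
        the ``min_observed_fraction`` gate); "fixed" divides by the full
        catalogue size regardless of missingness.

    Raises
    ------
    FrailtyUndefinedError
        If the observed fraction falls below ``schema.min_observed_fraction``.
    ValueError
        If the vector length does not match the schema.
    """
    arr = np.asarray(deficits)
    if arr.shape != (len(schema),):
        raise ValueError(
            f"deficit vector has length {arr.size}, schema has {len(schema)} items"
        )
    observed = arr != MISSING
    n_observed = int(observed.sum())
    if not np.isin(arr[observed], (0, 1)).all():
        raise ValueError("deficit values must be 0, 1 or MISSING")
    frac = n_observed / len(schema)
    if frac < schema.min_observed_fraction:
        raise FrailtyUndefinedError(
            f"only {n_observed}/{len(schema)} items observed "
            f"(< {schema.min_observed_fraction:.0%} required)"
        )
    n_def = int(arr[observed].sum())
    denom = len(schema) if denominator == "fixed" else n_observed
    return FrailtyScore(fi=n_def / denom, n_deficits=n_def, n_observed=n_observed)


def classify_frailty(fi: float, cutpoints) -> str:
    """Assign a severity category to a frailty-index value.

    Intervals are closed on the right: with boundaries ``(c1, .., ck)`` the
    categories are ``[0, c1], (c1, c2], .., (ck, 1]``. Total and
    deterministic on ``[0, 1]``.
    """
    if not (0.0 <= fi <= 1.0):
        raise ValueError(f"frailty index {fi} outside [0, 1]")
    bounds = list(cutpoints.boundaries)
    labels = list(cutpoints.labels)
    for b, lab in zip(bounds, labels):
        if fi <= b:
            return lab
    return labels[-1]


def score_cohort(
    cohort: pd.DataFrame,
    schema: DeficitSchema,
    denominator: DenominatorPolicy = "observed",
    cutpoints=None,
) -> pd.DataFrame:
    """Score every subject of a cohort table.

    ``cohort`` must carry one column per schema item id, with raw values
    the item coding rules understand. Returns a copy with ``fi``,
    ``n_deficits`` and ``n_observed`` columns appended (and ``category``
    when ``cutpoints`` is given). Subjects whose index is undefined under
    the missingness gate get ``NaN`` fi and are counted in the
    ``fi_undefined`` attribute of the returned frame (``.attrs``) — they
    are reported, never silently dropped.
    """
    missing_cols = [c for c in schema.item_ids if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks item columns: {missing_cols}")
    raw = cohort[schema.item_ids]
    coded = np.empty(raw.shape, dtype=np.int64)
    for j, item in enumerate(schema):
        col = raw.iloc[:, j]
        if item.coding.get("type", "binary") == "binary":
            vals = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            out = np.full(vals.shape, MISSING, dtype=np.int64)
            out[vals == 0.0] = 0
            out[vals == 1.0] = 1
            coded[:, j] = out
        else:
            coded[:, j] = [item.code(v) for v in col]

    observed = coded != MISSING
    n_observed = observed.sum(axis=1)
    n_def = np.where(observed, coded, 0).sum(axis=1)
    denom = (
        np.full(len(cohort), len(schema), dtype=float)
        if denominator == "fixed"
        else n_observed.astype(float)
    )
    ok = n_observed / len(schema) >= schema.min_observed_fraction
    fi = np.where(ok & (denom > 0), n_def / np.where(denom > 0, denom, 1), np.nan)

    out = cohort.copy()
    out["fi"] = fi
    out["n_deficits"] = n_def
    out["n_observed"] = n_observed
    if cutpoints is not None:
        out["category"] = pd.Categorical(
            [classify_frailty(v, cutpoints) if np.isfinite(v) else None for v in fi],
            categories=list(cutpoints.labels),
            ordered=True,
        )
    out.attrs["fi_undefined"] = int((~ok).sum())
    return out
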