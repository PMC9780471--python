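"""Stratum-specific likelihood ratios and severity-cutpoint derivation.

For a stratum ``s`` of a risk index, the stratum-specific likelihood
ratio (SSLR) is

    SSLR_s = P(s | died) / P(s | survived)
           = (x1_s / n1_overall) / (x0_s / n0_overall)

where ``x1_s``/``x0_s`` count deaths/survivors inside the stratum and
``n1_overall``/``n0_overall`` are the cohort totals. Values above 1 mark
strata enriched for death. Cutpoints between severity categories are
derived by testing each stratum's SSLR against the preceding stratum on
the log scale and merging adjacent strata that do not differ significantly.

Confidence intervals use the log-scale Wald form for a likelihood ratio
(Simel et al.):

    SE(ln SSLR) = sqrt(1/x1 - 1/n1_overall + 1/x0 - 1/n0_overall)
    CI = exp(ln SSLR ± z_{1-α/2} · SE)

The adjacent-stratum test is a two-sided z-test on the difference of log
SSLRs, treating strata as independent.

The procedure is exposed statsmodels-style: build an
:class:`SSLRCutpointModel` from per-stratum counts (or from subject-level
scores), call :meth:`~SSLRCutpointModel.fit`, and read the per-stratum
table, the retained boundaries and the merge trace off the returned
:class:`SSLRCutpointResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StratumSpec",
    "StratumCounts",
    "SSLREstimate",
    "CutpointSet",
    "SSLRCutpointModel",
    "SSLRCutpointResults",
    "stratify_cohort",
    "compute_sslr",
    "compare_adjacent_strata",
    "derive_cutpoints",
    "DEFAULT_CANDIDATE_BOUNDS",
    "SEVERITY_LABELS",
]

#: Candidate frailty-index boundaries commonly proposed for deficit indices.
DEFAULT_CANDIDATE_BOUNDS = (0.03, 0.10, 0.25, 0.30, 0.33, 0.45)

#: Canonical severity labels, least to most severe.
SEVERITY_LABELS = ("fit", "pre-frail", "mildly-frail", "severely-frail")


@dataclass(frozen=True)
class StratumSpec:
    """Half-open frailty-index interval ``(lower, upper]``.

    The first stratum additionally includes its lower endpoint so that an
    index of exactly 0 belongs to the lowest stratum.
    """

    lower: float
    upper: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"stratum needs lower < upper, got {self}")

    def __str__(self) -> str:
        return self.label or f">{self.lower:g}-<={self.upper:g}"


@dataclass(frozen=True)
class StratumCounts:
    """Death/survivor counts in one stratum plus the cohort totals."""

    spec: StratumSpec
    x1: int  # deaths in stratum
    x0: int  # survivors in stratum
    n1_overall: int  # total deaths in cohort
    n0_overall: int  # total survivors in cohort

    def __post_init__(self) -> None:
        if min(self.x1, self.x0) < 0:
            raise ValueError("counts must be non-negative")
        if self.x1 > self.n1_overall or self.x0 > self.n0_overall:
            raise ValueError("stratum counts exceed cohort totals")


@dataclass(frozen=True)
class SSLREstimate:
    """Point SSLR with log-scale SE and Wald CI."""

    sslr: float
    log_se: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    corrected: bool = False  # continuity correction applied to a zero cell


@dataclass(frozen=True)
class CutpointSet:
    """Ordered severity boundaries with category labels.

    ``len(labels) == len(boundaries) + 1``; ``provenance`` carries the
    per-boundary comparison records from the merge procedure.
    """

    boundaries: tuple[float, ...]
    labels: tuple[str, ...]
    provenance: tuple[dict, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        b = self.boundaries
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be strictly increasing")
        if any(not (0.0 < x < 1.0) for x in b):
            raise ValueError("boundaries must lie in (0, 1)")
        if len(self.labels) != len(b) + 1:
            raise ValueError("need exactly one more label than boundaries")


def _default_labels(k: int) -> tuple[str, ...]:
    if k <= len(SEVERITY_LABELS):
        return SEVERITY_LABELS[:k]
    return SEVERITY_LABELS + tuple(
        f"group-{i}" for i in range(len(SEVERITY_LABELS) + 1, k + 1)
    )


def stratify_cohort(
    fi: Sequence[float],
    event: Sequence[int],
    candidate_bounds: Sequence[float] = DEFAULT_CANDIDATE_BOUNDS,
) -> list[StratumCounts]:
    """Tabulate deaths and survivors per candidate frailty-index stratum.

    Candidate boundaries ``(c1, .., ck)`` induce strata ``[0, c1],
    (c1, c2], .., (ck, 1]``. Subjects with undefined (NaN) index are
    excluded with a warning carrying their count; counts tile the
    remaining cohort exactly, so per-stratum deaths and survivors sum to
    the overall totals. Empty strata are retained with zero counts.
    """
    fi = np.asarray(fi, dtype=float)
    event = np.asarray(event, dtype=int)
    if fi.shape != event.shape:
        raise ValueError("fi and event must be aligned")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event must be 0/1")
    defined = np.isfinite(fi)
    n_undef = int((~defined).sum())
    if n_undef:
        warnings.warn(
            f"excluding {n_undef} subjects with undefined frailty index",
            stacklevel=2,
        )
    fi, event = fi[defined], event[defined]
    if ((fi < 0) | (fi > 1)).any():
        raise ValueError("frailty index values must lie in [0, 1]")
    bounds = sorted(candidate_bounds)
    edges = [0.0, *bounds, 1.0]
    # np.digitize with right=True puts fi == boundary into the lower stratum;
    # fi == 0 lands in bin 0 because the first interval is closed at 0.
    idx = np.digitize(fi, edges[1:-1], right=True)
    n1, n0 = int(event.sum()), int((1 - event).sum())
    out: list[StratumCounts] = []
    for k in range(len(edges) - 1):
        lo, hi = edges[k], edges[k + 1]
        in_k = idx == k
        spec = StratumSpec(lo, hi, label=f"{'>' if k else ''}{lo:g}-<={hi:g}")
        out.append(
            StratumCounts(
                spec=spec,
                x1=int(event[in_k].sum()),
                x0=int((1 - event[in_k]).sum()),
                n1_overall=n1,
                n0_overall=n0,
            )
        )
    return out


def compute_sslr(counts: StratumCounts, alpha: float = 0.05) -> SSLREstimate:
    """Point SSLR with log-scale Wald CI for one stratum.

    A zero cell (no deaths or no survivors in the stratum) triggers the
    Haldane–Anscombe correction: 0.5 is added to both stratum cells and 1
    to both cohort totals, and the estimate is flagged ``corrected``.
    """
    if counts.n1_overall <= 0 or counts.n0_overall <= 0:
        raise ValueError("cohort totals must both be positive")
    x1, x0 = float(counts.x1), float(counts.x0)
    n1, n0 = float(counts.n1_overall), float(counts.n0_overall)
    corrected = x1 == 0 or x0 == 0
    if corrected:
        x1, x0, n1, n0 = x1 + 0.5, x0 + 0.5, n1 + 1.0, n0 + 1.0
    sslr = (x1 / n1) / (x0 / n0)
    log_se = float(np.sqrt(1.0 / x1 - 1.0 / n1 + 1.0 / x0 - 1.0 / n0))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    log_sslr = np.log(sslr)
    return SSLREstimate(
        sslr=float(sslr),
        log_se=log_se,
        ci_low=float(np.exp(log_sslr - z * log_se)),
        ci_high=float(np.exp(log_sslr + z * log_se)),
        alpha=alpha,
        corrected=corrected,
    )


def compare_adjacent_strata(a: SSLREstimate, b: SSLREstimate) -> float:
    """Two-sided p-value for H0: the two strata share one SSLR.

    z-test on the log scale: ``z = (ln b - ln a) / sqrt(se_a² + se_b²)``,
    treating the strata as independent.
    """
    se = float(np.hypot(a.log_se, b.log_se))
    if se == 0.0:
        if a.sslr == b.sslr:
            raise ValueError("degenerate comparison: both SEs are zero")
        return 0.0
    z = (np.log(b.sslr) - np.log(a.sslr)) / se
    return float(2.0 * stats.norm.sf(abs(z)))


class SSLRCutpointModel:
    """Severity-cutpoint derivation from stratified death counts.

    Parameters
    ----------
    strata : list of StratumCounts
        Ordered (by frailty index) strata tiling the cohort.

    Use :meth:`from_scores` to build the model directly from subject-level
    frailty indices and event indicators, or :meth:`from_table` from a
    pre-tabulated counts table (columns ``lower, upper, died, survived``).
    """

    def __init__(self, strata: Sequence[StratumCounts]):
        strata = list(strata)
        if len(strata) < 2:
            raise ValueError("need at least two strata")
        n1 = strata[0].n1_overall
        n0 = strata[0].n0_overall
        if any(s.n1_overall != n1 or s.n0_overall != n0 for s in strata):
            raise ValueError("all strata must share the same cohort totals")
        if sum(s.x1 for s in strata) != n1 or sum(s.x0 for s in strata) != n0:
            raise ValueError("stratum counts must sum to the cohort totals")
        self.strata = strata
        self.n1_overall = n1
        self.n0_overall = n0

    @classmethod
    def from_scores(
        cls,
        fi: Sequence[float],
        event: Sequence[int],
        candidate_bounds: Sequence[float] = DEFAULT_CANDIDATE_BOUNDS,
    ) -> "SSLRCutpointModel":
        return cls(stratify_cohort(fi, event, candidate_bounds))

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "SSLRCutpointModel":
        """Build from a counts table with columns lower, upper, died, survived."""
        required = {"lower", "upper", "died", "survived"}
        if not required.issubset(table.columns):
            raise ValueError(f"counts table needs columns {sorted(required)}")
        tab = table.sort_values("lower")
        n1 = int(tab["died"].sum())
        n0 = int(tab["survived"].sum())
        strata = [
            StratumCounts(
                spec=StratumSpec(float(r.lower), float(r.upper)),
                x1=int(r.died),
                x0=int(r.survived),
                n1_overall=n1,
                n0_overall=n0,
            )
            for r in tab.itertuples()
        ]
        return cls(strata)

    def fit(
        self,
        alpha: float = 0.05,
        recompute_after_merge: bool = False,
    ) -> "SSLRCutpointResults":
        """Run the estimate–test–merge procedure.

        Scans strata left to right; the boundary between strata ``k-1``
        and ``k`` is retained iff the adjacent z-test on the ORIGINAL
        (unmerged) strata gives ``p < alpha``. With
        ``recompute_after_merge`` each stratum is instead compared against
        the running merged group to its left.
        """
        estimates = [compute_sslr(s, alpha=alpha) for s in self.strata]
        trace: list[dict] = []
        boundaries: list[float] = []
        merged = self.strata[0]
        for k in range(1, len(self.strata)):
            if recompute_after_merge:
                left = compute_sslr(merged, alpha=alpha)
            else:
                left = estimates[k - 1]
            p = compare_adjacent_strata(left, estimates[k])
            significant = p < alpha
            trace.append(
                {
                    "boundary": self.strata[k].spec.lower,
                    "left": str(self.strata[k - 1].spec),
                    "right": str(self.strata[k].spec),
                    "p_value": p,
                    "significant": significant,
                }
            )
            if significant:
                boundaries.append(self.strata[k].spec.lower)
                merged = self.strata[k]
            else:
                merged = StratumCounts(
                    spec=StratumSpec(merged.spec.lower, self.strata[k].spec.upper),
                    x1=merged.x1 + self.strata[k].x1,
                    x0=merged.x0 + self.strata[k].x0,
                    n1_overall=self.n1_overall,
                    n0_overall=self.n0_overall,
                )
        if not boundaries:
            warnings.warn(
                "no adjacent strata differ significantly; returning a "
                "single severity group",
                stacklevel=2,
            )
        cutpoints = CutpointSet(
            boundaries=tuple(boundaries),
            labels=_default_labels(len(boundaries) + 1),
            provenance=tuple(trace),
        )
        return SSLRCutpointResults(self, estimates, cutpoints, alpha)


class SSLRCutpointResults:
    """Fitted cutpoint procedure: per-stratum SSLR table and boundaries."""

    def __init__(
        self,
        model: SSLRCutpointModel,
        estimates: list[SSLREstimate],
        cutpoints: CutpointSet,
        alpha: float,
    ):
        self.model = model
        self.estimates = estimates
        self.cutpoints = cutpoints
        self.alpha = alpha

    @property
    def sslr_table(self) -> pd.DataFrame:
        """Per-stratum table mirroring the standard presentation."""
        rows = []
        p_by_boundary = {t["boundary"]: t for t in self.cutpoints.provenance}
        for s, e in zip(self.model.strata, self.estimates):
            t = p_by_boundary.get(s.spec.lower)
            rows.append(
                {
                    "stratum": str(s.spec),
                    "lower": s.spec.lower,
                    "upper": s.spec.upper,
                    "died": s.x1,
                    "survived": s.x0,
                    "sslr": e.sslr,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "p_vs_preceding": t["p_value"] if t else np.nan,
                    "significant": bool(t["significant"]) if t else False,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report of the fitted procedure."""
        tab = self.sslr_table
        lines = [
            "Stratum-specific likelihood ratio cutpoint derivation",
            f"  cohort: {self.model.n1_overall} deaths, "
            f"{self.model.n0_overall} survivors, alpha={self.alpha:g}",
            "",
            f"  {'stratum':<16}{'died':>6}{'surv':>7}{'SSLR':>7}"
            f"{'95% CI':>16}{'p(adj)':>9}",
        ]
        for r in tab.itertuples():
            mark = "*" if r.significant else " "
            p = "" if np.isnan(r.p_vs_preceding) else f"{r.p_vs_preceding:9.4f}"
            lines.append(
                f"  {r.stratum:<16}{r.died:>6}{r.survived:>7}{r.sslr:>7.2f}"
                f"{f'{r.ci_low:.2f} to {r.ci_high:.2f}':>16}{p:>9}{mark}"
            )
        lines.append("")
        if self.cutpoints.boundaries:
            b = ", ".join(f"{x:g}" for x in self.cutpoints.boundaries)
            lines.append(f"  retained boundaries: {b}")
            lines.append(f"  categories: {', '.join(self.cutpoints.labels)}")
        else:
            lines.append("  no boundaries retained (single group)")
        lines.append("  (* p < alpha vs preceding stratum)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serialisable report."""
        return {
            "alpha": self.alpha,
            "n1_overall": self.model.n1_overall,
            "n0_overall": self.model.n0_overall,
            "strata": self.sslr_table.to_dict(orient="records"),
            "boundaries": list(self.cutpoints.boundaries),
            "labels": list(self.cutpoints.labels),
            "merge_trace": [dict(t) for t in self.cutpoints.provenance],
        }


def derive_cutpoints(
    strata: Sequence[StratumCounts],
    alpha: float = 0.05,
    recompute_after_merge: bool = False,
) -> CutpointSet:
    """Functional wrapper around :class:`SSLRCutpointModel`."""
    return (
        SSLRCutpointModel(strata)
        .fit(alpha=alpha, recompute_after_merge=recompute_after_merge)
        .cutpoints
    )
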