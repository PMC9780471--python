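"""Survival validation of frailty categories against mortality.

Person-time death rates, Kaplan–Meier curves per severity category,
covariate-adjusted Cox proportional-hazards models (category coefficients
expressed against the fittest group), per-stratum subgroup model tables,
and Harrell's concordance index with a paired-bootstrap comparison of two
risk scores.

Cox fitting is delegated to statsmodels' proportional-hazards regression;
the default tie handling is Breslow, with Efron selectable. Kaplan–Meier
estimation uses lifelines; concordance uses scikit-survival's censored
pair counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from sksurv.metrics import concordance_index_censored
import statsmodels.api as sm

__all__ = [
    "CoxResult",
    "ConcordanceResult",
    "person_time_rates",
    "kaplan_meier",
    "fit_cox",
    "subgroup_table",
    "concordance",
    "compare_concordance",
]


@dataclass
class CoxResult:
    """Fitted Cox proportional-hazards model.

    ``params`` are log-hazard coefficients; ``hazard_ratios`` their
    exponentials with Wald CIs. ``converged`` is False when the optimiser
    failed or the fit shows signs of monotone likelihood (separation),
    in which case the estimates are reported but flagged.
    """

    params: pd.Series
    bse: pd.Series
    hazard_ratios: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p_values: pd.Series
    n: int
    n_events: int
    tie_method: str
    converged: bool = True
    warnings_: list[str] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "HR": self.hazard_ratios,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p_values,
            }
        )

    def summary(self) -> str:
        head = (
            f"Cox PH fit (ties={self.tie_method}): n={self.n}, "
            f"events={self.n_events}, converged={self.converged}"
        )
        return head + "\n" + self.summary_frame().to_string(float_format="%.4f")


@dataclass(frozen=True)
class ConcordanceResult:
    """Harrell's C for a risk score under right censoring."""

    c_index: float
    n_comparable_pairs: int
    concordant: int
    discordant: int
    tied_risk: int


def person_time_rates(
    data: pd.DataFrame,
    group_col: str = "category",
    time_col: str = "follow_up_time",
    event_col: str = "event",
    per: float = 1000.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Death rate per ``per`` person-years, by group.

    The CI is the exact Poisson (chi-square) interval on the event count
    divided by the observed person-time.
    """
    rows = []
    for grp, sub in data.groupby(group_col, sort=True, observed=True):
        pt = float(sub[time_col].sum())
        if pt <= 0:
            raise ValueError(f"group {grp!r} has zero person-time")
        d = int(sub[event_col].sum())
        lo = stats.chi2.ppf(alpha / 2, 2 * d) / 2 if d > 0 else 0.0
        hi = stats.chi2.ppf(1 - alpha / 2, 2 * d + 2) / 2
        rows.append(
            {
                group_col: grp,
                "events": d,
                "person_years": pt,
                "rate": d / pt * per,
                "rate_ci_low": lo / pt * per,
                "rate_ci_high": hi / pt * per,
            }
        )
    return pd.DataFrame(rows).set_index(group_col)


def kaplan_meier(
    data: pd.DataFrame,
    group_col: str | None = "category",
    time_col: str = "follow_up_time",
    event_col: str = "event",
) -> dict[str, KaplanMeierFitter]:
    """Product-limit survival estimate per group.

    Returns one fitted :class:`lifelines.KaplanMeierFitter` per group
    (a single entry keyed ``"all"`` when ``group_col`` is None), each a
    right-continuous decreasing step function.
    """
    if len(data) == 0:
        raise ValueError("empty dataset")
    groups = (
        {"all": data}
        if group_col is None
        else {str(k): v for k, v in data.groupby(group_col, sort=True, observed=True)}
    )
    out = {}
    for label, sub in groups.items():
        kmf = KaplanMeierFitter(label=label)
        kmf.fit(sub[time_col], event_observed=sub[event_col])
        out[label] = kmf
    return out


def plot_kaplan_meier(fits: dict[str, KaplanMeierFitter], path: str) -> None:
    """Write a Kaplan–Meier plot of the fitted groups to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for kmf in fits.values():
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("years of follow-up")
    ax.set_ylabel("survival probability")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _design_matrix(
    data: pd.DataFrame,
    covariates: list[str],
    category_col: str | None,
    reference: str,
) -> pd.DataFrame:
    cols = []
    if category_col is not None:
        cats = pd.Categorical(data[category_col])
        if reference not in cats.categories:
            raise ValueError(
                f"reference category {reference!r} absent from {category_col!r}"
            )
        ordered = [reference] + [c for c in cats.categories if c != reference]
        dummies = pd.get_dummies(
            pd.Categorical(data[category_col], categories=ordered), dtype=float
        ).iloc[:, 1:]
        dummies.columns = [f"{category_col}[{c}]" for c in dummies.columns]
        dummies.index = data.index
        cols.append(dummies)
    for cov in covariates:
        if cov not in data.columns:
            raise ValueError(f"covariate {cov!r} not in data")
        cols.append(pd.to_numeric(data[cov]).rename(cov).astype(float))
    if not cols:
        raise ValueError("no covariates to fit")
    X = pd.concat(cols, axis=1)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    return X


def fit_cox(
    data: pd.DataFrame,
    covariates: list[str] | None = None,
    category_col: str | None = "category",
    reference: str = "fit",
    time_col: str = "follow_up_time",
    event_col: str = "event",
    tie_method: str = "breslow",
    alpha: float = 0.05,
) -> CoxResult:
    """Fit a Cox proportional-hazards model by partial likelihood.

    Frailty-category indicator coefficients are expressed against the
    ``reference`` category; additional ``covariates`` enter linearly.
    Tie handling is Breslow by default (Efron selectable). Monotone
    likelihood (separation) is detected from runaway coefficients and
    reported through ``converged``/``warnings_`` rather than silently.
    """
    if tie_method not in ("breslow", "efron"):
        raise ValueError("tie_method must be 'breslow' or 'efron'")
    event = np.asarray(data[event_col], dtype=int)
    time = np.asarray(data[time_col], dtype=float)
    if (time <= 0).any():
        raise ValueError("follow-up times must be positive")
    if len(np.unique(time[event == 1])) < 2:
        raise ValueError("need at least two distinct event times")
    X = _design_matrix(data, covariates or [], category_col, reference)

    model = sm.PHReg(time, X.to_numpy(), status=event, ties=tie_method)
    notes: list[str] = []
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(disp=False)
        except Exception as exc:  # noqa: BLE001 - surfaced, not swallowed
            raise RuntimeError(f"Cox fit failed: {exc}") from exc
    for w in caught:
        notes.append(str(w.message))
        if "convergence" in str(w.message).lower():
            converged = False
    params = pd.Series(res.params, index=X.columns)
    bse = pd.Series(res.bse, index=X.columns)
    if not np.isfinite(params).all() or not np.isfinite(bse).all():
        converged = False
        notes.append("non-finite estimates")
    if (params.abs() > 10).any() or (bse > 50).any():
        converged = False
        notes.append("possible monotone likelihood (separation)")
    z = stats.norm.ppf(1 - alpha / 2)
    return CoxResult(
        params=params,
        bse=bse,
        hazard_ratios=np.exp(params),
        ci_low=np.exp(params - z * bse),
        ci_high=np.exp(params + z * bse),
        p_values=pd.Series(2 * stats.norm.sf(np.abs(params / bse)), index=X.columns),
        n=len(X),
        n_events=int(event.sum()),
        tie_method=tie_method,
        converged=converged,
        warnings_=notes,
    )


def subgroup_table(
    data: pd.DataFrame,
    strat_var: str,
    **fit_kwargs,
) -> dict[str, CoxResult | None]:
    """One Cox fit per level of a stratification variable (same formula).

    Strata with no events (or too few distinct event times) are flagged
    with ``None`` and a warning instead of aborting the table.
    """
    out: dict[str, CoxResult | None] = {}
    for level, sub in data.groupby(strat_var, sort=True, observed=True):
        try:
            out[str(level)] = fit_cox(sub, **fit_kwargs)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"stratum {level!r} skipped: {exc}", stacklevel=2)
            out[str(level)] = None
    return out


def concordance(
    data: pd.DataFrame,
    risk_score,
    time_col: str = "follow_up_time",
    event_col: str = "event",
) -> ConcordanceResult:
    """Harrell's C-index of a risk score against censored survival.

    Counts comparable pairs under right censoring (the earlier time must
    be an event); tied risk scores contribute 1/2.
    """
    risk = np.asarray(risk_score, dtype=float)
    event = np.asarray(data[event_col], dtype=bool)
    time = np.asarray(data[time_col], dtype=float)
    try:
        c, conc, disc, tied_r, _tied_t = concordance_index_censored(event, time, risk)
    except ValueError as exc:
        raise ValueError(f"no comparable pairs: {exc}") from exc
    n_pairs = int(conc + disc + tied_r)
    if n_pairs == 0:
        raise ValueError("no comparable pairs (all censored?)")
    return ConcordanceResult(
        c_index=float(c),
        n_comparable_pairs=n_pairs,
        concordant=int(conc),
        discordant=int(disc),
        tied_risk=int(tied_r),
    )


def compare_concordance(
    data: pd.DataFrame,
    score_a,
    score_b,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    time_col: str = "follow_up_time",
    event_col: str = "event",
) -> dict:
    """Paired-bootstrap comparison of two risk scores' C-indices.

    Resamples subjects with replacement, recomputes both C-indices on each
    resample, and tests ``H0: C_a == C_b`` with a normal approximation on
    the bootstrap SE of the difference. Returns the observed C-indices,
    the difference, its bootstrap SE and the two-sided p-value.
    """
    rng = np.random.default_rng(seed)
    score_a = np.asarray(score_a, dtype=float)
    score_b = np.asarray(score_b, dtype=float)
    ca = concordance(data, score_a, time_col, event_col).c_index
    cb = concordance(data, score_b, time_col, event_col).c_index
    n = len(data)
    time = np.asarray(data[time_col], dtype=float)
    event = np.asarray(data[event_col], dtype=bool)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if event[idx].sum() == 0:
            diffs[b] = np.nan
            continue
        ca_b = concordance_index_censored(event[idx], time[idx], score_a[idx])[0]
        cb_b = concordance_index_censored(event[idx], time[idx], score_b[idx])[0]
        diffs[b] = ca_b - cb_b
    diffs = diffs[np.isfinite(diffs)]
    se = float(diffs.std(ddof=1))
    delta = ca - cb
    if se == 0.0:
        p = 1.0 if delta == 0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(delta) / se))
    return {
        "c_a": ca,
        "c_b": cb,
        "delta": delta,
        "bootstrap_se": se,
        "p_value": p,
        "n_boot": int(len(diffs)),
    }
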