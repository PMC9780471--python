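"""End-to-end analysis driver: score → derive cutpoints → validate.

Takes a cohort table, computes frailty indices against a deficit schema,
derives severity cutpoints by the SSLR merge procedure, and validates the
resulting categories against mortality (person-time rates, Cox models
with optional subgroup stratification, concordance). Emits one
machine-readable report; all randomness (bootstrap) flows from a single
seed with deterministically derived child seeds.
"""

from __future__ import annotations

import json
import sys
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .schema import DeficitSchema, load_schema
from .scoring import score_cohort
from .sslr import DEFAULT_CANDIDATE_BOUNDS, CutpointSet, SSLRCutpointModel
from .survival import (
    concordance,
    fit_cox,
    kaplan_meier,
    person_time_rates,
    subgroup_table,
)
from .wealth import wealth_quintiles

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run."""

    schema: str | DeficitSchema = "default"
    candidate_bounds: Sequence[float] = DEFAULT_CANDIDATE_BOUNDS
    alpha: float = 0.05
    adjust: Sequence[str] = ("age", "smoking_ever", "wealth_quintile")
    subgroups: Sequence[str] = ("gender", "caretaker")
    tie_method: str = "breslow"
    denominator: str = "observed"
    asset_columns: Sequence[str] | None = None  # auto-detected "asset_*" if None
    seed: int = 0

    def resolve_schema(self) -> DeficitSchema:
        if isinstance(self.schema, DeficitSchema):
            return self.schema
        return load_schema(self.schema)


def _cox_to_report(res) -> dict | None:
    if res is None:
        return None
    frame = res.summary_frame()
    return {
        "n": res.n,
        "n_events": res.n_events,
        "tie_method": res.tie_method,
        "converged": res.converged,
        "warnings": res.warnings_,
        "terms": {
            name: {
                "coef": float(row["coef"]),
                "se": float(row["se"]),
                "hr": float(row["HR"]),
                "ci_low": float(row["ci_low"]),
                "ci_high": float(row["ci_high"]),
                "p": float(row["p"]),
            }
            for name, row in frame.iterrows()
        },
    }


def run_pipeline(cohort: pd.DataFrame, config: PipelineConfig | None = None) -> dict:
    """Run the full analysis on a cohort table and return the report.

    Stages are tagged in errors so a failure names where it happened;
    the report accumulates stage outputs as they complete.
    """
    cfg = config or PipelineConfig()
    schema = cfg.resolve_schema()
    report: dict = {
        "frailtykit_version": __version__,
        "python": sys.version.split()[0],
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "n_subjects": int(len(cohort)),
    }

    stage = "wealth"
    try:
        if "wealth_quintile" not in cohort.columns:
            asset_cols = list(cfg.asset_columns or [])
            if not asset_cols:
                asset_cols = [c for c in cohort.columns if c.startswith("asset_")]
            if asset_cols:
                wq = wealth_quintiles(cohort[asset_cols])
                cohort = cohort.copy()
                cohort[["wealth_score", "wealth_quintile"]] = wq.to_numpy()
            elif "wealth_quintile" in cfg.adjust:
                raise ValueError(
                    "no wealth_quintile column and no asset columns to build one"
                )

        stage = "score"
        scored = score_cohort(cohort, schema, denominator=cfg.denominator)
        report["fi_undefined"] = scored.attrs["fi_undefined"]
        report["fi_summary"] = {
            "mean": float(np.nanmean(scored["fi"])),
            "median": float(np.nanmedian(scored["fi"])),
            "max": float(np.nanmax(scored["fi"])),
        }

        stage = "derive-cutpoints"
        defined = scored[np.isfinite(scored["fi"])]
        model = SSLRCutpointModel.from_scores(
            defined["fi"], defined["event"], cfg.candidate_bounds
        )
        cut_res = model.fit(alpha=cfg.alpha)
        report["sslr"] = cut_res.to_dict()
        cutpoints = cut_res.cutpoints

        stage = "validate"
        scored["category"] = [
            _classify(v, cutpoints) for v in scored["fi"]
        ]
        cat_order = [c for c in cutpoints.labels if c in set(scored["category"])]
        scored["category"] = pd.Categorical(
            scored["category"], categories=cat_order, ordered=True
        )
        report["rates_per_1000py"] = (
            person_time_rates(scored).round(6).reset_index().to_dict(orient="records")
        )
        report["crude_mortality"] = {
            str(cat): float(sub["event"].mean())
            for cat, sub in scored.groupby("category", observed=True)
        }
        adjust = [c for c in cfg.adjust if c in scored.columns]
        overall = fit_cox(
            scored,
            covariates=adjust,
            category_col="category",
            reference=cat_order[0],
            tie_method=cfg.tie_method,
        )
        report["cox"] = {"overall": _cox_to_report(overall), "adjusted_for": adjust}
        for var in cfg.subgroups:
            if var not in scored.columns:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sub = subgroup_table(
                    scored,
                    var,
                    covariates=[c for c in adjust if c != var],
                    category_col="category",
                    reference=cat_order[0],
                    tie_method=cfg.tie_method,
                )
            report["cox"][f"by_{var}"] = {
                k: _cox_to_report(v) for k, v in sub.items()
            }

        stage = "concordance"
        conc = concordance(defined, defined["fi"])
        report["concordance"] = {
            "c_index": conc.c_index,
            "n_comparable_pairs": conc.n_comparable_pairs,
        }
        # survival curves are fitted but only summarised in the report
        km = kaplan_meier(scored)
        report["km_final_survival"] = {
            k: float(f.survival_function_.iloc[-1, 0]) for k, f in km.items()
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report


def _classify(fi: float, cutpoints: CutpointSet) -> str | None:
    from .scoring import classify_frailty

    if not np.isfinite(fi):
        return None
    return classify_frailty(fi, cutpoints)


def write_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=str)
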