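"""End-to-end analysis: free IL-18 -> cutoff -> group table -> survival.

Reproduces the analysis sequence of the dichotomized-biomarker infection
study on any cohort in the canonical CSV schema:

1. derive free IL-18 from total IL-18 and IL-18BP by mass action (skipped
   when the column is already present);
2. ROC of free IL-18 against the infection label and Youden cutoff selection
   (or a user-fixed cutoff such as the published 6.0 pmol/l);
3. dichotomization with strict ``<``;
4. baseline group comparisons (chi-square for the event counts,
   Mann-Whitney for quantitative variables);
5. Kaplan-Meier curves per group and the two-group log-rank test;
6. Cox proportional hazards adjusted for the configured covariates, with a
   variance-inflation-factor collinearity check.

The report is a plain nested dict, deterministic given the input and config
(the provenance timestamp is the only non-deterministic field).
"""

from __future__ import annotations

import hashlib
import json
import sys
import time as _time
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from . import __version__
from .cohort import COHORT_COLUMNS, _check_schema
from .equilibrium import DEFAULT_KD_PMOL_L, solve_equilibrium
from .marker_stats import (
    Contingency2x2,
    chi_square_2x2,
    confusion_at_cutoff,
    mann_whitney_u,
    roc_curve,
    youden_cutoff,
)
from .survival import check_collinearity, cox_fit, km_estimate, log_rank

__all__ = ["AnalysisConfig", "PipelineError", "run_pipeline", "report_hash"]

#: Default adjustment covariates for the Cox model (the published model's
#: full covariate set).
DEFAULT_COX_COVARIATES = [
    "egfr",
    "crp",
    "age",
    "albumin",
    "hemoglobin",
    "corrected_ca",
    "phosphate",
    "intact_pth",
]

_QUANT_VARS = [
    "total_il18_pmol_l",
    "il18bp_pmol_l",
    "free_il18_pmol_l",
] + DEFAULT_COX_COVARIATES


class PipelineError(RuntimeError):
    """The pipeline could not proceed (schema problem or degenerate cohort)."""


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline.

    ``cutoff=None`` selects the threshold by the Youden index; a number
    (e.g. 6.0 pmol/l) fixes it.  ``kd`` is the dissociation constant used
    when free IL-18 must be derived.  ``covariates`` are the Cox adjustment
    variables (column names in the cohort CSV).
    """

    kd: float = DEFAULT_KD_PMOL_L
    cutoff: float | None = None
    orientation: str = "low_predicts_event"
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COX_COVARIATES))
    ties: str = "breslow"
    alpha: float = 0.05
    seed: int | None = None  # recorded in provenance when the cohort was simulated

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _log(msg: str, *, quiet: bool) -> None:
    if not quiet:
        print(msg, file=sys.stderr)


def run_pipeline(cohort, config: AnalysisConfig | None = None, *, quiet: bool = True) -> dict:
    """Run the full analysis; returns the report as a nested dict.

    ``cohort`` is a DataFrame in the canonical schema (``free_il18_pmol_l``
    optional — it is recomputed from the totals when absent).  Raises
    :class:`PipelineError` when the schema is invalid or the cohort has no
    events (after stage 1, with an explicit diagnostic).
    """
    cfg = config or AnalysisConfig()
    df = cohort.copy()

    t0 = _time.perf_counter()
    optional_free = [c for c in COHORT_COLUMNS if c != "free_il18_pmol_l"]
    missing = [c for c in optional_free if c not in df.columns]
    if missing:
        raise PipelineError(f"cohort is missing required columns: {missing}")

    # stage 1: free IL-18
    if "free_il18_pmol_l" not in df.columns:
        state = solve_equilibrium(
            df["total_il18_pmol_l"].to_numpy(float),
            df["il18bp_pmol_l"].to_numpy(float),
            cfg.kd,
        )
        df["free_il18_pmol_l"] = state.free_ligand
    violations = _check_schema(df)
    if violations:
        raise PipelineError("cohort schema invalid: " + "; ".join(violations))
    free = df["free_il18_pmol_l"].to_numpy(float)
    event = df["event"].to_numpy(int)
    time_days = df["time_days"].to_numpy(float)
    n = len(df)
    _log(f"[stage 1] free IL-18 ready for {n} records "
         f"({_time.perf_counter() - t0:.2f}s)", quiet=quiet)

    if event.sum() < 1:
        raise PipelineError(
            "no infection events in the cohort: ROC, log-rank and Cox stages "
            "are undefined; halting after free IL-18 computation"
        )

    # stage 2: ROC + cutoff
    t1 = _time.perf_counter()
    curve = roc_curve(free, event, cfg.orientation)
    if cfg.cutoff is None:
        cut = youden_cutoff(curve)
        cutoff, cutoff_source = cut.cutoff, "youden"
    else:
        cutoff, cutoff_source = float(cfg.cutoff), "fixed"
    conf = confusion_at_cutoff(free, event, cutoff, cfg.orientation)
    _log(f"[stage 2] ROC auc={curve.auc:.3f}, cutoff={cutoff:.3g} "
         f"({cutoff_source}) ({_time.perf_counter() - t1:.2f}s)", quiet=quiet)

    # stage 3: dichotomization (strict <)
    low = free < cutoff if cfg.orientation == "low_predicts_event" else free > cutoff
    n_low, n_high = int(low.sum()), int((~low).sum())

    # stage 4: group comparisons
    t2 = _time.perf_counter()
    ev_low = int(event[low].sum())
    ev_high = int(event[~low].sum())
    try:
        chi2_stat, chi2_p = chi_square_2x2(
            Contingency2x2(ev_low, ev_high, n_low - ev_low, n_high - ev_high)
        )
    except ValueError:
        chi2_stat, chi2_p = None, None
    variables = {}
    for var in _QUANT_VARS:
        if var not in df.columns:
            continue
        vals = df[var].to_numpy(float)
        a, b = vals[low], vals[~low]
        if a.size and b.size:
            _, mw_p = mann_whitney_u(a, b)
        else:
            mw_p = None
        variables[var] = {
            "low_mean": float(np.mean(a)) if a.size else None,
            "low_sd": float(np.std(a, ddof=1)) if a.size > 1 else None,
            "high_mean": float(np.mean(b)) if b.size else None,
            "high_sd": float(np.std(b, ddof=1)) if b.size > 1 else None,
            "p_mann_whitney": mw_p,
        }
    _log(f"[stage 4] group table over {len(variables)} variables "
         f"({_time.perf_counter() - t2:.2f}s)", quiet=quiet)

    # stage 5: KM + log-rank
    t3 = _time.perf_counter()
    km_low = km_estimate(time_days[low], event[low]) if n_low else None
    km_high = km_estimate(time_days[~low], event[~low]) if n_high else None
    if n_low and n_high:
        lr = log_rank(time_days, event, low.astype(int))
        logrank = {"statistic": lr.statistic, "p": lr.p_value, "df": lr.df}
    else:
        logrank = None
    _log(f"[stage 5] log-rank ({_time.perf_counter() - t3:.2f}s)", quiet=quiet)

    # stage 6: adjusted Cox (complete-case per model)
    t4 = _time.perf_counter()
    covs = [c for c in cfg.covariates if c in df.columns]
    design = pd.DataFrame({"low_free_il18": low.astype(float)})
    for c in covs:
        design[c] = df[c].to_numpy(float)
    complete = design.notna().all(axis=1).to_numpy()
    n_excluded = int((~complete).sum())
    cox_section: dict = {"n_excluded_missing": n_excluded}
    try:
        vif = check_collinearity(
            design.loc[complete].to_numpy(), list(design.columns)
        ) if design.shape[1] >= 2 else None
        fit = cox_fit(
            design.loc[complete],
            time_days[complete],
            event[complete],
            ties=cfg.ties,
            alpha=cfg.alpha,
        )
        cox_section.update(
            {
                "converged": fit.converged,
                "n_iter": fit.n_iter,
                "log_likelihood": fit.log_likelihood,
                "ties": fit.ties,
                "fits": fit.to_records(),
                "vif": vif.to_dict("records") if vif is not None else None,
            }
        )
    except ValueError as exc:
        cox_section.update({"converged": False, "error": str(exc), "fits": []})
    _log(f"[stage 6] Cox over {len(design.columns)} covariates "
         f"({_time.perf_counter() - t4:.2f}s)", quiet=quiet)

    report = {
        "cohort": {
            "n": n,
            "n_events": int(event.sum()),
            "total_il18_mean": float(df["total_il18_pmol_l"].mean()),
            "total_il18_sd": float(df["total_il18_pmol_l"].std(ddof=1)),
            "il18bp_mean": float(df["il18bp_pmol_l"].mean()),
            "il18bp_sd": float(df["il18bp_pmol_l"].std(ddof=1)),
            "free_il18_mean": float(df["free_il18_pmol_l"].mean()),
            "free_il18_sd": float(df["free_il18_pmol_l"].std(ddof=1)),
        },
        "roc": {
            "auc": curve.auc,
            "cutoff": cutoff,
            "cutoff_source": cutoff_source,
            "sensitivity": conf.sensitivity,
            "specificity": conf.specificity,
            "display": {
                "auc": round(curve.auc, 2),
                "sensitivity_pct": _pct(conf.sensitivity),
                "specificity_pct": _pct(conf.specificity),
            },
        },
        "groups": {
            "cutoff": cutoff,
            "n_low": n_low,
            "n_high": n_high,
            "events_low": ev_low,
            "events_high": ev_high,
            "event_pct_low": _pct(ev_low / n_low if n_low else None),
            "event_pct_high": _pct(ev_high / n_high if n_high else None),
            "event_pct_overall": _pct(event.sum() / n),
            "chi2_statistic": chi2_stat,
            "chi2_p": chi2_p,
            "variables": variables,
        },
        "survival": {
            "logrank": logrank,
            "km_low": km_low.to_frame().to_dict("list") if km_low else None,
            "km_high": km_high.to_frame().to_dict("list") if km_high else None,
        },
        "cox": cox_section,
        "provenance": {
            "config_hash": cfg.hash(),
            "seed": cfg.seed,
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
    }
    return report


def _pct(fraction) -> float | None:
    return None if fraction is None else round(100.0 * fraction, 1)


def report_hash(report: dict) -> str:
    """Hash of the deterministic part of a report (timestamp excluded)."""
    clipped = {k: v for k, v in report.items() if k != "provenance"}
    clipped["provenance"] = {
        k: v for k, v in report["provenance"].items() if k != "timestamp"
    }
    return hashlib.sha256(
        json.dumps(clipped, sort_keys=True, default=str).encode()
    ).hexdigest()
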