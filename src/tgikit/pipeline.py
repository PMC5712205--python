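"""End-to-end analysis steps tying the modules together.

These helpers implement the standard flow — fit the population model under
one alignment, derive per-patient metrics, pair them with the matching
survival outcome (OS forward, OS - PFS reverse) and assess concordance —
so the CLI, the tests and user scripts all run the same code path.
"""

from __future__ import annotations

from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .alignment import post_progression_table
from .kinetic_model import derive_metrics
from .population_fit import FitConfig, PopulationFit, fit_population
from .survival_stats import ConcordanceResult, bootstrap_ci, concordance_probability, fit_cox
from .trial_sim import METRIC_DIRECTIONS

__all__ = [
    "metrics_table",
    "fit_and_derive",
    "progressor_assessments",
    "outcome_table",
    "concordance_analysis",
    "individual_risk",
    "patient_metric_table",
]


def metrics_table(fit: PopulationFit) -> pd.DataFrame:
    """Per-patient metric table (DR, GR, TTG, TTN, pct_change_w8) from a fit."""
    rows = []
    for pid, params in fit.individual_params.items():
        span = fit.observation_spans[pid]
        m = derive_metrics(params, fit.alignment, span)
        rows.append(
            (pid, fit.alignment, m.DR, m.GR, m.TTG, m.TTN, m.pct_change_w8, span)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "alignment", "DR", "GR", "TTG", "TTN",
            "pct_change_w8", "span_weeks",
        ],
    )


def fit_and_derive(
    assessments: pd.DataFrame,
    alignment: str = "forward",
    config: Optional[FitConfig] = None,
) -> Tuple[PopulationFit, pd.DataFrame]:
    """Population fit plus the derived per-patient metric table."""
    fit = fit_population(assessments, alignment=alignment, config=config)
    return fit, metrics_table(fit)


def progressor_assessments(
    assessments: pd.DataFrame, survival: pd.DataFrame
) -> pd.DataFrame:
    """Assessments restricted to patients with an observed radiological
    progression (reverse-alignment analyses are anchored at progression, so
    non-progressors and progression-by-death patients have no origin)."""
    flags = survival["pfs_event"] == 1
    if "progression_is_death" in survival.columns:
        flags &= survival["progression_is_death"] == 0
    keep = set(survival.loc[flags, "patient_id"])
    return assessments.loc[assessments["patient_id"].isin(keep)].copy()


def outcome_table(survival: pd.DataFrame, alignment: str) -> pd.DataFrame:
    """Outcome used under the given alignment, per patient.

    Forward: overall survival for every patient.  Reverse: OS - PFS for
    progressed patients, dropping the progression-by-death records (their
    post-progression time is zero by construction).
    """
    if alignment == "forward":
        return pd.DataFrame(
            {
                "patient_id": survival["patient_id"],
                "time_weeks": survival["os_weeks"].astype(float),
                "event": survival["os_event"].astype(int),
            }
        )
    pp = post_progression_table(survival)
    pp = pp.loc[~pp["excluded"] & (pp["time_weeks"] > 0)]
    return pp[["patient_id", "time_weeks", "event"]].reset_index(drop=True)


def concordance_analysis(
    metric_values: pd.DataFrame,
    direction: str,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> ConcordanceResult:
    """Cox fit + signed CP with a percentile bootstrap over patients.

    ``metric_values`` has columns ``value, time_weeks, event``; each
    bootstrap replicate refits the Cox coefficient on the resampled cohort
    before recomputing the CP (apparent CP, as in the source analyses).
    """

    def statistic(df: pd.DataFrame) -> float:
        cox = fit_cox(
            df["value"].to_numpy(float),
            df["time_weeks"].to_numpy(float),
            df["event"].to_numpy(float),
        )
        return concordance_probability(cox.beta, df["value"].to_numpy(float), direction)

    return bootstrap_ci(
        statistic, metric_values, n_boot=n_boot, seed=seed, direction=direction
    )


def individual_risk(
    metrics: pd.DataFrame,
    survival: pd.DataFrame,
    alignment: str,
    metric_names: Iterable[str] = ("GR", "TTG"),
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Concordance results for each metric under one alignment.

    Returns one row per metric with the CP, its bootstrap 95% CI and the
    significance flag (CI excludes 0.5), plus the number of patients used
    and of progression-by-death exclusions (reverse only).
    """
    outcomes = outcome_table(survival, alignment)
    merged_base = metrics.merge(outcomes, on="patient_id", how="inner")
    n_excluded = 0
    if alignment == "reverse":
        pp = post_progression_table(survival)
        n_excluded = int((pp["excluded"] | (pp["time_weeks"] <= 0)).sum())
    rows = []
    seeds = np.random.SeedSequence(seed).spawn(len(tuple(metric_names)))
    for metric, ss in zip(metric_names, seeds):
        direction = METRIC_DIRECTIONS[metric]
        data = merged_base[[metric, "time_weeks", "event"]].rename(
            columns={metric: "value"}
        )
        res = concordance_analysis(
            data, direction, n_boot=n_boot, seed=int(ss.generate_state(1)[0] % 2**31)
        )
        rows.append(
            (
                metric, alignment, res.cp, res.ci_low, res.ci_high, res.significant,
                res.direction, len(data), n_excluded,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "metric", "alignment", "cp", "ci_low", "ci_high", "significant",
            "direction", "n_patients", "n_excluded",
        ],
    )


def patient_metric_table(
    metrics: pd.DataFrame, survival: pd.DataFrame
) -> pd.DataFrame:
    """Merge per-patient metrics with survival for the trial resampler."""
    return metrics.merge(survival, on="patient_id", how="inner")
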