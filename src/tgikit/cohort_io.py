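"""Readers/writers for the tabular formats and trial-report-style summaries.

Files are plain RFC-4180 CSV with a documented header; every file written by
the package carries leading ``#`` comment lines recording the package
version, the seed and a hash of the configuration that produced it, and the
readers skip such lines.  Times are stored in weeks at 4-decimal precision;
summaries report Kaplan-Meier medians in months.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from . import __version__
from .alignment import post_progression_table
from .kinetic_model import weeks_to_months
from .survival_stats import MedianSurvival, km_median

__all__ = [
    "CohortSummary",
    "read_assessments",
    "read_survival",
    "write_table",
    "summarize_cohort",
    "dropout_assessment",
    "config_hash",
]

ASSESSMENT_COLUMNS = ["patient_id", "time_weeks", "sld_cm"]
SURVIVAL_COLUMNS = ["patient_id", "pfs_weeks", "pfs_event", "os_weeks", "os_event"]


def config_hash(config) -> str:
    """Short stable hash of a configuration mapping/dataclass."""
    if hasattr(config, "__dataclass_fields__"):
        config = asdict(config)
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path,
    seed: Optional[int] = None,
    config=None,
    float_format: str = "%.4f",
) -> None:
    """Write a CSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# tgikit v{__version__}\n")
        fh.write(f"# seed={seed}\n")
        fh.write(f"# config={config_hash(config) if config is not None else 'none'}\n")
        df.to_csv(fh, index=False, float_format=float_format)


def _read_csv(path, required, numeric):
    df = pd.read_csv(path, comment="#")
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    for col in numeric:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna() & df[col].notna()].tolist()
        if bad:
            raise ValueError(f"{path}: non-numeric {col!r} in rows {bad[:10]}")
        df[col] = values
    return df


def read_assessments(path) -> pd.DataFrame:
    """Read and validate a long-format assessment table.

    Rejects missing columns, negative times, non-positive SLD and
    duplicated ``(patient_id, time_weeks)`` keys, reporting offending row
    indices (0-based, excluding header/comment lines).
    """
    df = _read_csv(path, ASSESSMENT_COLUMNS, ["time_weeks", "sld_cm"])
    problems = []
    neg = df.index[df["time_weeks"] < 0].tolist()
    if neg:
        problems.append(f"negative time_weeks in rows {neg[:10]}")
    bad_sld = df.index[~(df["sld_cm"] > 0)].tolist()
    if bad_sld:
        problems.append(f"non-positive sld_cm in rows {bad_sld[:10]}")
    dup = df.index[df.duplicated(["patient_id", "time_weeks"], keep=False)].tolist()
    if dup:
        problems.append(f"duplicate (patient_id, time_weeks) in rows {dup[:10]}")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    return df[ASSESSMENT_COLUMNS + [c for c in df.columns if c not in ASSESSMENT_COLUMNS]]


def read_survival(path) -> pd.DataFrame:
    """Read and validate a per-patient survival table."""
    df = _read_csv(
        path, SURVIVAL_COLUMNS, ["pfs_weeks", "pfs_event", "os_weeks", "os_event"]
    )
    problems = []
    dup = df.index[df.duplicated(["patient_id"], keep=False)].tolist()
    if dup:
        problems.append(f"duplicate patient_id in rows {dup[:10]}")
    nonpos = df.index[(df["pfs_weeks"] <= 0) | (df["os_weeks"] <= 0)].tolist()
    if nonpos:
        problems.append(f"non-positive survival times in rows {nonpos[:10]}")
    order = df.index[df["os_weeks"] < df["pfs_weeks"]].tolist()
    if order:
        problems.append(f"os_weeks < pfs_weeks in rows {order[:10]}")
    for col in ("pfs_event", "os_event"):
        bad = df.index[~df[col].isin([0, 1])].tolist()
        if bad:
            problems.append(f"{col} not 0/1 in rows {bad[:10]}")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))
    return df


@dataclass(frozen=True)
class CohortSummary:
    """Trial-report-style description of one trial arm.

    Medians for PFS, OS and OS - PFS are Kaplan-Meier estimates in months
    (NaN when the curve never reaches 0.5, e.g. immature OS data); the
    observed percent change uses each patient's first scan in weeks 6-10.
    """

    n_total: int
    n_death_events: int
    n_progression_events: int
    n_progressions_by_death: int
    median_baseline_sld: float
    iqr_baseline_sld: tuple
    median_pct_change_w6_10: float
    iqr_pct_change_w6_10: tuple
    km_pfs_months: MedianSurvival
    km_os_months: MedianSurvival
    km_os_minus_pfs_months: MedianSurvival

    def to_dict(self) -> dict:
        out = asdict(self)
        for key in ("km_pfs_months", "km_os_months", "km_os_minus_pfs_months"):
            out[key] = asdict(getattr(self, key))
        return out


def _km_months(time_weeks, event) -> MedianSurvival:
    est = km_median(np.asarray(time_weeks, dtype=float), np.asarray(event))
    return MedianSurvival(
        *(float(weeks_to_months(v)) if not math.isnan(v) else math.nan
          for v in (est.median, est.ci_low, est.ci_high))
    )


def summarize_cohort(assessments: pd.DataFrame, survival: pd.DataFrame) -> CohortSummary:
    """Compute the cohort summary from the assessment and survival tables."""
    ids_a = set(assessments["patient_id"])
    ids_s = set(survival["patient_id"])
    if not ids_a & ids_s:
        raise ValueError("assessment and survival tables share no patients")

    baselines = (
        assessments.sort_values("time_weeks").groupby("patient_id").first()["sld_cm"]
    )
    pct_changes = []
    for pid, rows in assessments.groupby("patient_id"):
        rows = rows.sort_values("time_weeks")
        t = rows["time_weeks"].to_numpy(dtype=float)
        y = rows["sld_cm"].to_numpy(dtype=float)
        window = np.flatnonzero((t >= 6.0) & (t <= 10.0) & (t > 0))
        if window.size:
            pct_changes.append(100.0 * (y[window[0]] - y[0]) / y[0])
    pct_changes = np.asarray(pct_changes)

    if "progression_is_death" in survival.columns:
        by_death = int(
            ((survival["pfs_event"] == 1) & (survival["progression_is_death"] == 1)).sum()
        )
    else:
        by_death = int(
            (
                (survival["pfs_event"] == 1)
                & (survival["os_event"] == 1)
                & (survival["os_weeks"] == survival["pfs_weeks"])
            ).sum()
        )

    pp = post_progression_table(survival)
    pp_ok = pp.loc[~pp["excluded"] & (pp["time_weeks"] > 0)]
    if len(pp_ok) and (pp_ok["event"] == 1).any():
        km_pp = _km_months(pp_ok["time_weeks"], pp_ok["event"])
    else:
        km_pp = MedianSurvival(math.nan, math.nan, math.nan)

    return CohortSummary(
        n_total=int(len(survival)),
        n_death_events=int((survival["os_event"] == 1).sum()),
        n_progression_events=int((survival["pfs_event"] == 1).sum()),
        n_progressions_by_death=by_death,
        median_baseline_sld=float(np.median(baselines)),
        iqr_baseline_sld=tuple(np.percentile(baselines, [25, 75])),
        median_pct_change_w6_10=(
            float(np.median(pct_changes)) if pct_changes.size else math.nan
        ),
        iqr_pct_change_w6_10=(
            tuple(np.percentile(pct_changes, [25, 75]))
            if pct_changes.size
            else (math.nan, math.nan)
        ),
        km_pfs_months=_km_months(survival["pfs_weeks"], survival["pfs_event"]),
        km_os_months=_km_months(survival["os_weeks"], survival["os_event"]),
        km_os_minus_pfs_months=km_pp,
    )


def dropout_assessment(survival: pd.DataFrame, level: float = 0.95):
    """Proportion of progression events that are deaths, with exact
    (Clopper-Pearson) binomial CI.

    This is the check that decides whether the imaging drop-out mechanism
    is informative of survival: when the proportion is small, drop-out
    marks treatment discontinuation rather than death, and a joint
    longitudinal-survival model is not needed.
    """
    if "progression_is_death" not in survival.columns:
        raise ValueError("survival table lacks 'progression_is_death' flags")
    prog = survival.loc[survival["pfs_event"] == 1]
    n = len(prog)
    if n == 0:
        raise ValueError("no progression events")
    k = int((prog["progression_is_death"] == 1).sum())
    ci = binomtest(k, n).proportion_ci(confidence_level=level, method="exact")
    return k / n, (float(ci.low), float(ci.high)), k, n
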