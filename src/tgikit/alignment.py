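"""Forward / reverse alignment of SLD time series and survival outcomes.

Forward alignment indexes a patient's scans from treatment start and pairs
the kinetic metrics with overall survival (OS).  Reverse alignment re-indexes
the scans from the time of progression, with the clock running into the past,
and pairs the metrics with post-progression survival (OS - PFS).  Reversing
removes the guarantee-time bias of TTG/GR: under forward alignment the time
needed to *estimate* the metrics is itself part of the outcome.

Conventions
-----------
* The reversed clock is non-negative: observation time ``s_i = t_last - t_i``
  with the observations re-ordered so times ascend from 0.  This is a pure
  reflection of the series about its last scan, so the same model code fits
  both alignments, and applying it twice restores the original series.
* The imaging origin for reversal is the last scan of the series (imaging
  stops at progression under the trial protocols), while the survival
  subtraction uses the recorded PFS time; the small gap between the last
  scan date and the PFS date is ignored.
* Patients whose progression event *is* death (OS == PFS, both observed)
  have no post-progression follow-up; they are flagged for exclusion from
  reverse-alignment survival analyses and the count of exclusions is always
  available to callers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "AlignedSeries",
    "PostProgressionRecord",
    "series_from_assessments",
    "reverse_align_series",
    "post_progression_survival",
    "post_progression_table",
]


@dataclass(frozen=True)
class AlignedSeries:
    """One patient's SLD series on a single clock.

    ``times`` start at 0 and are strictly increasing; ``progression_time``
    is on the forward clock (weeks from treatment start) regardless of the
    alignment tag, so that reversal is an involution.
    """

    patient_id: str
    alignment: str
    times: np.ndarray
    sld: np.ndarray
    progression_time: Optional[float]
    observation_span: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        sld = np.asarray(self.sld, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "sld", sld)
        if self.alignment not in ("forward", "reverse"):
            raise ValueError(f"bad alignment tag {self.alignment!r}")
        if times.ndim != 1 or times.shape != sld.shape:
            raise ValueError("times and sld must be 1-D arrays of equal length")
        if times.size == 0:
            raise ValueError("series must contain at least one observation")
        if abs(times[0]) > 1e-9:
            raise ValueError("aligned times must start at 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("aligned times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


def series_from_assessments(
    assessments: pd.DataFrame,
    patient_id: str,
    progression_time: Optional[float] = None,
) -> AlignedSeries:
    """Build a forward-aligned series from long-format assessment rows."""
    rows = assessments.loc[assessments["patient_id"] == patient_id]
    if rows.empty:
        raise ValueError(f"no assessments for patient {patient_id!r}")
    rows = rows.sort_values("time_weeks")
    times = rows["time_weeks"].to_numpy(dtype=float)
    times = times - times[0]
    return AlignedSeries(
        patient_id=str(patient_id),
        alignment="forward",
        times=times,
        sld=rows["sld_cm"].to_numpy(dtype=float),
        progression_time=progression_time,
        observation_span=float(times[-1] - times[0]),
    )


def reverse_align_series(series: AlignedSeries) -> AlignedSeries:
    """Reflect a series about its last scan, toggling the alignment tag.

    The reversed times are ``t_last - t_i`` in descending-``i`` order, so
    they ascend from 0 (the scan at/closest before progression); the SLD
    values travel with their scans.  Gaps between consecutive scans and the
    observation span are preserved, and applying the function twice returns
    the original series.
    """
    if len(series) < 2:
        raise ValueError("reversal needs at least two observations")
    if series.alignment == "forward" and series.progression_time is None:
        raise ValueError(
            f"patient {series.patient_id}: cannot reverse-align without a "
            "progression time"
        )
    new_times = series.times[-1] - series.times[::-1]
    return replace(
        series,
        alignment="reverse" if series.alignment == "forward" else "forward",
        times=new_times,
        sld=series.sld[::-1].copy(),
    )


@dataclass(frozen=True)
class PostProgressionRecord:
    """Post-progression survival (OS - PFS) for one progressed patient."""

    patient_id: str
    time: float
    event: int
    excluded: bool  # progression event was death: no post-progression time


def post_progression_survival(
    os_time: float,
    os_event: int,
    pfs_time: float,
    pfs_event: int,
    patient_id: str = "",
    progression_is_death: Optional[bool] = None,
) -> PostProgressionRecord:
    """OS - PFS with OS's event indicator, for one patient.

    Requires an observed progression (``pfs_event == 1``) and
    ``os_time >= pfs_time``.  When the progression event was itself the
    patient's death (``progression_is_death``, or inferred from
    ``os_time == pfs_time`` with both events observed), the record is
    flagged ``excluded``: there is no post-progression interval to analyse.
    """
    if pfs_event != 1:
        raise ValueError(f"patient {patient_id!r}: progression not observed")
    if os_time < pfs_time:
        raise ValueError(
            f"patient {patient_id!r}: OS time {os_time} precedes PFS time {pfs_time}"
        )
    if progression_is_death is None:
        progression_is_death = bool(os_time == pfs_time and os_event == 1)
    return PostProgressionRecord(
        patient_id=str(patient_id),
        time=float(os_time - pfs_time),
        event=int(os_event),
        excluded=bool(progression_is_death),
    )


def post_progression_table(survival: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`post_progression_survival` over a survival table.

    Keeps only patients with an observed progression; returns columns
    ``patient_id, time_weeks, event, excluded``.  Callers should drop the
    ``excluded`` rows from reverse-alignment analyses and report the count.
    """
    prog = survival.loc[survival["pfs_event"] == 1].copy()
    if (prog["os_weeks"] < prog["pfs_weeks"]).any():
        bad = prog.loc[prog["os_weeks"] < prog["pfs_weeks"], "patient_id"].tolist()
        raise ValueError(f"OS precedes PFS for patients {bad}")
    if "progression_is_death" in prog.columns:
        excluded = prog["progression_is_death"].astype(bool)
    else:
        excluded = (prog["os_weeks"] == prog["pfs_weeks"]) & (prog["os_event"] == 1)
    return pd.DataFrame(
        {
            "patient_id": prog["patient_id"].to_numpy(),
            "time_weeks": (prog["os_weeks"] - prog["pfs_weeks"]).to_numpy(dtype=float),
            "event": prog["os_event"].to_numpy(dtype=int),
            "excluded": excluded.to_numpy(dtype=bool),
        }
    )
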