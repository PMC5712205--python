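"""Biexponential tumour-size kinetics and the metrics derived from it.

The sum-of-longest-diameters (SLD) trajectory of a treated solid tumour is
modelled as the superposition of a shrinking and a re-growing exponential,

    SLD(t) = A * (exp(-B*t) + exp(C*t) - 1)

with ``A`` the baseline SLD in cm and ``B``, ``C`` strictly positive rates per
week.  The trajectory has a unique minimum (the nadir) at the turning point

    tp = (log(B) - log(C)) / (B + C)

which may be negative (profile monotonically growing on-study) or beyond the
observation window (monotonically shrinking).

Two time alignments are used throughout the package.  In *forward* time the
origin is treatment start, ``B`` plays the role of the decay rate DR and ``C``
the re-growth rate GR, and the turning point is the time-to-re-growth TTG.  In
*reverse* time the series runs backwards from disease progression, the roles of
the two rates swap (GR = B, DR = C), and the turning point is the time-to-nadir
TTN measured back from the last scan; TTG is then the observation span minus
TTN.

All functions are pure; time is in weeks everywhere (reporting converts to
months with :data:`WEEKS_PER_MONTH`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "WEEKS_PER_MONTH",
    "KineticParams",
    "TumorMetrics",
    "sld_at",
    "turning_point",
    "pct_change_model",
    "derive_metrics",
    "weeks_to_months",
    "months_to_weeks",
]

logger = logging.getLogger(__name__)

#: Average weeks per calendar month (30.4375 days / 7); used only for reporting.
WEEKS_PER_MONTH = 30.4375 / 7.0


def weeks_to_months(weeks):
    """Convert a duration in weeks to calendar months."""
    return np.asarray(weeks, dtype=float) / WEEKS_PER_MONTH


def months_to_weeks(months):
    """Convert a duration in calendar months to weeks."""
    return np.asarray(months, dtype=float) * WEEKS_PER_MONTH


@dataclass(frozen=True)
class KineticParams:
    """One patient's biexponential parameters.

    Attributes
    ----------
    A : float
        Baseline SLD (cm), > 0.
    B : float
        First-phase rate (per week), > 0.  Decay rate in forward time.
    C : float
        Second-phase rate (per week), > 0.  Re-growth rate in forward time.

    All three are strictly positive, consistent with the log-normal
    population distribution assumed by the mixed-effects fit.
    """

    A: float
    B: float
    C: float

    def __post_init__(self) -> None:
        for name in ("A", "B", "C"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(
                    f"KineticParams.{name} must be finite and > 0, got {value!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C], dtype=float)

    def log_array(self) -> np.ndarray:
        return np.log(self.as_array())


@dataclass(frozen=True)
class TumorMetrics:
    """Model-derived metrics for one patient under a given alignment.

    ``DR``/``GR`` are the decay and re-growth rates after applying the
    alignment role convention; ``TTG`` is clamped to ``[0, span]`` (forward)
    or derived as ``span - TTN`` (reverse).  ``TTN`` is populated only for
    reverse alignment.  ``pct_change_w8`` is the model-predicted percent
    change from baseline at week 8 and does not depend on ``A``.
    """

    alignment: str
    DR: float
    GR: float
    TTG: float
    pct_change_w8: float
    TTN: Optional[float] = None


def sld_at(params: KineticParams, t):
    """Evaluate the biexponential SLD model at time ``t`` (weeks).

    ``t`` may be a scalar or array; negative times are permitted (they are
    used by reflection/symmetry checks).
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time must be finite")
    out = params.A * (np.exp(-params.B * t) + np.exp(params.C * t) - 1.0)
    return float(out) if out.ndim == 0 else out


def turning_point(params: KineticParams) -> float:
    """Time of the trajectory's nadir, ``(log B - log C) / (B + C)`` weeks.

    This is the unique global minimiser of :func:`sld_at` over the real
    line; it is negative when ``B < C`` (the profile grows monotonically for
    ``t >= 0``).
    """
    return (math.log(params.B) - math.log(params.C)) / (params.B + params.C)


def pct_change_model(params: KineticParams, t) -> float:
    """Model-predicted percent change from baseline at time ``t >= 0``.

    Equals ``100 * (exp(-B t) + exp(C t) - 2)``; independent of ``A``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("pct_change_model requires t >= 0")
    out = 100.0 * (np.exp(-params.B * t) + np.exp(params.C * t) - 2.0)
    return float(out) if out.ndim == 0 else out


def derive_metrics(
    params: KineticParams, alignment: str, observation_span: float
) -> TumorMetrics:
    """Derive DR, GR and TTG (and TTN in reverse time) from fitted parameters.

    Parameters
    ----------
    params
        Fitted biexponential parameters for one patient, in the clock of the
        series they were fitted to.
    alignment
        ``"forward"`` (origin at treatment start) or ``"reverse"`` (origin at
        progression, clock running into the past).
    observation_span
        Time from first to last assessment used in this patient's fit, weeks.

    Notes
    -----
    The turning point may fall outside ``[0, observation_span]`` for
    monotone profiles; it is clamped to that interval (logged at DEBUG
    level), which keeps TTG well defined and bounded.
    """
    if alignment not in ("forward", "reverse"):
        raise ValueError(f"alignment must be 'forward' or 'reverse', got {alignment!r}")
    if not (math.isfinite(observation_span) and observation_span > 0):
        raise ValueError(f"observation_span must be > 0, got {observation_span!r}")

    tp = turning_point(params)
    tp_clamped = min(max(tp, 0.0), observation_span)
    if tp_clamped != tp:
        logger.debug(
            "turning point %.4f clamped to [0, %.4f] (%s alignment)",
            tp,
            observation_span,
            alignment,
        )
    pct8 = pct_change_model(params, 8.0)

    if alignment == "forward":
        return TumorMetrics(
            alignment="forward",
            DR=params.B,
            GR=params.C,
            TTG=tp_clamped,
            pct_change_w8=pct8,
            TTN=None,
        )
    # reverse: B decays away from the progression origin, i.e. it is the
    # re-growth rate of the original clock; the nadir time is TTN and
    # TTG = span - TTN.
    return TumorMetrics(
        alignment="reverse",
        DR=params.C,
        GR=params.B,
        TTG=observation_span - tp_clamped,
        pct_change_w8=pct8,
        TTN=tp_clamped,
    )
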