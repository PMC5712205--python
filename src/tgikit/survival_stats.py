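"""Proportional-hazards fitting, concordance probability, KM summaries.

The individual-risk question — does a kinetic metric predict survival? — is
answered with a model-based concordance probability (CP) in the style of
Gonen & Heller (2005): a Cox proportional-hazards coefficient ``beta`` is
estimated for the metric, and every unordered patient pair contributes the
model-implied probability that the patient with the *better* metric value
(direction pre-specified per metric) outlives the other,

    P = 1 / (1 + exp(eta_better - eta_other)),   eta_i = beta * x_i,

with tied covariate values contributing 1/2.  Censoring enters through the
Cox fit only.  The estimator is *signed*: when the fitted coefficient points
against the pre-specified benefit direction the CP drops below 0.5, which an
unsigned pairwise estimator cannot do.  CP = 0.5 means no consistent
relationship; significance is judged by whether a 95% percentile bootstrap
interval (patient resampling, 1,000 replicates by default) excludes 0.5.

The Cox partial likelihood (Efron tie handling) is maximised by a Newton
iteration specialised to a single covariate; this keeps the bootstrap and
trial-resampling loops, where the Cox fit is the innermost operation, fast.
Kaplan-Meier medians and their log-log confidence intervals come from
lifelines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times

__all__ = [
    "CoxResult",
    "ConcordanceResult",
    "MedianSurvival",
    "HazardRatioResult",
    "fit_cox",
    "concordance_probability",
    "bootstrap_ci",
    "km_median",
    "hazard_ratio",
]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class CoxResult:
    """Single-covariate Cox fit: coefficient, SE, and diagnostics."""

    beta: float
    se: float
    loglik: float
    n: int
    n_events: int
    converged: bool

    @property
    def hr(self) -> float:
        return math.exp(self.beta)


@dataclass(frozen=True)
class ConcordanceResult:
    """Concordance probability with percentile-bootstrap 95% bounds."""

    cp: float
    ci_low: float
    ci_high: float
    n_boot: int
    significant: bool  # CI excludes 0.5
    direction: str


@dataclass(frozen=True)
class MedianSurvival:
    """Kaplan-Meier median with log-log CI; NaN when the curve never
    reaches 0.5 (median not estimable)."""

    median: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class HazardRatioResult:
    hr: float
    ci_low: float
    ci_high: float
    beta: float
    se: float


def _prepare(x, time, event):
    x = np.asarray(x, dtype=float)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=float)
    if not (x.shape == t.shape == d.shape) or x.ndim != 1:
        raise ValueError("covariate, time and event must be 1-D arrays of equal length")
    if x.size == 0:
        raise ValueError("empty survival data")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite covariate values")
    if np.any(t <= 0):
        raise ValueError("survival times must be strictly positive")
    if not np.isin(d, (0.0, 1.0)).all():
        raise ValueError("event indicator must be 0/1")
    return x, t, d.astype(bool)


def _efron_quantities(beta, xs, xe, suffix_source, starts, m_rep, frac, first_risk):
    """Log-likelihood, gradient and Hessian of the Efron partial likelihood.

    ``xs`` are covariates sorted by time ascending; ``xe`` the event-row
    covariates in the same order, grouped by tied event time.  ``frac`` is
    the flattened Efron correction fraction l/m for each within-group rank.
    """
    eta = np.clip(beta * xs, -500.0, 500.0)
    w = np.exp(eta)
    wx = w * xs
    wxx = wx * xs
    # risk-set (suffix) sums evaluated at each tied-event-time group
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1])[::-1]
    s2 = np.cumsum(wxx[::-1])[::-1]
    S0 = s0[first_risk]
    S1 = s1[first_risk]
    S2 = s2[first_risk]
    we = np.exp(np.clip(beta * xe, -500.0, 500.0))
    T0 = np.add.reduceat(we, starts)
    T1 = np.add.reduceat(we * xe, starts)
    T2 = np.add.reduceat(we * xe * xe, starts)

    phi0 = S0[m_rep] - frac * T0[m_rep]
    phi1 = S1[m_rep] - frac * T1[m_rep]
    phi2 = S2[m_rep] - frac * T2[m_rep]

    loglik = beta * xe.sum() - np.log(phi0).sum()
    ratio = phi1 / phi0
    grad = xe.sum() - ratio.sum()
    hess = -(phi2 / phi0 - ratio * ratio).sum()
    return loglik, grad, hess


def fit_cox(
    covariate,
    time,
    event,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> CoxResult:
    """Maximise the Cox partial likelihood for one covariate (Efron ties).

    Deterministic Newton iteration with step halving, started at beta = 0.
    The covariate is centred internally for numerical stability (the
    partial likelihood is invariant to location shifts).

    Raises ``ValueError`` when there are no events.  A constant covariate
    is a degenerate design: the fit returns ``beta = 0`` with infinite SE,
    flagged ``converged=False``.
    """
    x, t, d = _prepare(covariate, time, event)
    n_events = int(d.sum())
    if n_events == 0:
        raise ValueError("no events: Cox model not estimable")
    if np.ptp(x) == 0.0:
        warnings.warn("constant covariate: Cox coefficient not identifiable")
        return CoxResult(0.0, math.inf, math.nan, x.size, n_events, False)

    x = x - x.mean()
    order = np.argsort(t, kind="stable")
    xs = t[order], x[order], d[order]
    ts, xs, ds = xs[0], xs[1], xs[2]
    te = ts[ds]
    xe = xs[ds]
    starts = np.flatnonzero(np.r_[True, np.diff(te) > 0])
    m = np.diff(np.r_[starts, te.size])
    first_risk = np.searchsorted(ts, te[starts], side="left")
    # flattened Efron rank fractions l/m, l = 0..m_k-1 per group
    m_rep = np.repeat(np.arange(m.size), m)
    ranks = np.arange(m.sum()) - np.repeat(np.cumsum(m) - m, m)
    frac = ranks / m[m_rep]

    beta = 0.0
    loglik, grad, hess = _efron_quantities(beta, xs, xe, None, starts, m_rep, frac, first_risk)
    converged = False
    for _ in range(max_iter):
        if hess >= 0:  # should not happen away from degeneracy
            break
        step = -grad / hess
        # step halving to guarantee ascent
        for _ in range(30):
            cand = beta + step
            ll_new, g_new, h_new = _efron_quantities(
                cand, xs, xe, None, starts, m_rep, frac, first_risk
            )
            if ll_new >= loglik - 1e-12:
                break
            step *= 0.5
        delta = cand - beta
        beta, loglik, grad, hess = cand, ll_new, g_new, h_new
        if abs(grad) < tol or abs(delta) < 1e-12:
            converged = True
            break
    if not converged and abs(grad) < 1e-6:
        converged = True
    if not converged:
        raise RuntimeError(
            f"Cox fit did not converge: beta={beta:.4g}, |grad|={abs(grad):.3g}"
        )
    se = math.inf if hess >= 0 else 1.0 / math.sqrt(-hess)
    return CoxResult(float(beta), float(se), float(loglik), x.size, n_events, True)


def concordance_probability(beta: float, covariates, direction: str = "higher") -> float:
    """Signed model-based concordance probability.

    Parameters
    ----------
    beta
        Proportional-hazards coefficient fitted to these covariates.
    covariates
        Metric values, one per patient.
    direction
        Pre-specified benefit direction of the metric: ``"higher"`` (e.g.
        TTG — longer time to re-growth is better) or ``"lower"`` (e.g. GR —
        slower re-growth is better).

    Each unordered pair with distinct values contributes
    ``1 / (1 + exp(beta * (x_better - x_other)))``; tied pairs contribute
    1/2.  With ``beta = 0`` the result is exactly 0.5.
    """
    if direction not in ("higher", "lower"):
        raise ValueError(f"direction must be 'higher' or 'lower', got {direction!r}")
    x = np.asarray(covariates, dtype=float)
    if x.size == 0:
        raise ValueError("empty covariate vector")
    if x.size == 1:
        raise ValueError("concordance needs at least two patients")
    sign = 1.0 if direction == "higher" else -1.0
    # pair contribution depends only on |x_i - x_j|:
    # eta_better - eta_other = beta * sign * |dx|
    dx = np.abs(x[:, None] - x[None, :])
    iu = np.triu_indices(x.size, k=1)
    z = np.clip(sign * beta * dx[iu], -500.0, 500.0)
    contrib = 1.0 / (1.0 + np.exp(z))
    return float(contrib.mean())


def bootstrap_ci(
    statistic: Callable[[pd.DataFrame], float],
    cohort: pd.DataFrame,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: Optional[int] = None,
    direction: str = "higher",
    rng: Optional[np.random.Generator] = None,
) -> ConcordanceResult:
    """Percentile bootstrap of a scalar statistic over patient resampling.

    Resamples the cohort's rows (patients) with replacement at the original
    size ``n_boot`` times and returns the point estimate on the full cohort
    together with the percentile interval at ``level``.  ``significant`` is
    True when the interval excludes 0.5 (the no-relationship value of a
    concordance probability).  Replicates on which the statistic raises or
    returns NaN are dropped; more than 10% of failures aborts.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(cohort)
    if n == 0:
        raise ValueError("empty cohort")
    point = float(statistic(cohort))
    values = np.empty(n_boot)
    n_failed = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            v = float(statistic(cohort.iloc[idx]))
        except Exception:
            v = math.nan
        if math.isnan(v):
            n_failed += 1
        values[b] = v
    if n_failed > 0.1 * n_boot:
        raise RuntimeError(
            f"bootstrap statistic failed on {n_failed}/{n_boot} replicates"
        )
    ok = values[~np.isnan(values)]
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(ok, [alpha, 100.0 - alpha])
    return ConcordanceResult(
        cp=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        significant=bool(lo > 0.5 or hi < 0.5),
        direction=direction,
    )


def km_median(time, event, level: float = 0.95) -> MedianSurvival:
    """Kaplan-Meier median survival with log-log (exp-Greenwood) CI.

    Returns NaN components when the survival curve never drops to 0.5
    (median not reached) or when a CI bound never does.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=float)
    if t.size == 0:
        raise ValueError("empty survival data")
    kmf = KaplanMeierFitter(alpha=1.0 - level)
    kmf.fit(t, event_observed=d)
    med = kmf.median_survival_time_
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])

    def _clean(v: float) -> float:
        return math.nan if math.isinf(v) else float(v)

    return MedianSurvival(_clean(med), _clean(lo), _clean(hi))


def hazard_ratio(arm_test: pd.DataFrame, arm_reference: pd.DataFrame) -> HazardRatioResult:
    """Hazard ratio of the test arm vs the reference arm with Wald 95% CI.

    Both arms are DataFrames with ``time_weeks`` and ``event`` columns; the
    arm indicator (1 = test) is the single Cox covariate, so ``hr < 1``
    favours the test arm.
    """
    for name, arm in (("test", arm_test), ("reference", arm_reference)):
        if (np.asarray(arm["event"]) == 1).sum() == 0:
            raise ValueError(f"{name} arm has no events")
    time = np.concatenate(
        [arm_test["time_weeks"].to_numpy(float), arm_reference["time_weeks"].to_numpy(float)]
    )
    event = np.concatenate(
        [arm_test["event"].to_numpy(float), arm_reference["event"].to_numpy(float)]
    )
    x = np.concatenate([np.ones(len(arm_test)), np.zeros(len(arm_reference))])
    fit = fit_cox(x, time, event)
    return HazardRatioResult(
        hr=math.exp(fit.beta),
        ci_low=math.exp(fit.beta - _Z95 * fit.se),
        ci_high=math.exp(fit.beta + _Z95 * fit.se),
        beta=fit.beta,
        se=fit.se,
    )
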