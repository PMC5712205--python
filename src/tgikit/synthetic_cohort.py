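"""Synthetic NSCLC trial arms with the structure the analysis assumes.

Each patient's SLD follows the biexponential law with log-normal
inter-individual variability on (A, B, C), observed on a fixed scan grid
with additive Gaussian measurement noise.  Progression is a simplified
RECIST rule — first scan with SLD at least ``(1 + threshold)`` times the
running nadir — and imaging stops at progression, mirroring the trial
protocols.  A small per-interval death hazard during imaging produces the
minority of progression events that are deaths.  Post-progression survival
(OS - PFS) follows either an exponential law independent of the kinetics
(the *null* model: tumour dynamics before progression carry no information
about what happens after) or a *linked* model whose log-hazard is a linear
function of the true GR and TTG.

The default :func:`docetaxel_like` arm emulates a second-line docetaxel
comparator arm: ~400 patients, 8-weekly scans, median baseline SLD ≈ 8.3 cm,
near-zero median % change at the first on-treatment scan, median PFS around
4 months, median post-progression survival around 5 months, and < 10% of
progression events being deaths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .kinetic_model import KineticParams, sld_at, turning_point

__all__ = [
    "CohortSpec",
    "apply_progression",
    "generate_cohort",
    "docetaxel_like",
    "erlotinib_like",
    "paclitaxel_carboplatin_like",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic trial arm.

    ``mu``/``omega2`` are the log-scale population location and (diagonal)
    variance of (A, B, C); ``sigma`` the additive measurement-noise SD in
    cm.  ``post_progression`` selects the OS - PFS model: ``"null"`` draws
    an exponential time with rate ``pp_rate`` independent of the kinetics,
    ``"linked"`` multiplies that rate by ``exp(gamma_gr*GR + gamma_ttg*TTG)``
    using the patient's true metrics.  ``death_during_imaging_prob`` is the
    per-scan-interval probability of death before progression, producing
    the small progression-by-death subset.
    """

    n_patients: int = 399
    scan_interval: float = 8.0  # weeks; trials used 6- or 8-weekly imaging
    max_followup: float = 96.0  # imaging horizon, weeks
    mu: Tuple[float, float, float] = (
        math.log(8.3),
        math.log(0.04),
        math.log(0.0303),
    )
    omega2: Tuple[float, float, float] = (0.40, 0.64, 0.64)
    sigma: float = 0.3  # cm
    progression_threshold: float = 0.20  # fractional rise over nadir
    post_progression: str = "null"
    pp_rate: float = _LN2 / 22.6  # per week; median OS - PFS ~= 5.2 months
    gamma_gr: float = 0.0
    gamma_ttg: float = 0.0
    death_during_imaging_prob: float = 0.015  # per scan interval
    random_pd_prob: float = 0.0  # optional non-target/new-lesion PD hazard
    censoring_time: float = 130.0  # administrative OS censoring, weeks
    scan_jitter: float = 0.0  # half-width of uniform scan-time jitter, weeks
    sld_floor: float = 0.1  # minimum measurable SLD, cm
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.scan_interval <= 0 or self.max_followup <= 0:
            raise ValueError("scan_interval and max_followup must be > 0")
        if self.progression_threshold <= 0:
            raise ValueError("progression_threshold must be > 0")
        if self.sigma < 0 or self.pp_rate <= 0 or self.censoring_time <= 0:
            raise ValueError("sigma >= 0, pp_rate > 0, censoring_time > 0 required")
        if any(v < 0 for v in self.omega2):
            raise ValueError("omega2 entries must be >= 0")
        if not 0 <= self.death_during_imaging_prob < 1:
            raise ValueError("death_during_imaging_prob must be in [0, 1)")
        if not 0 <= self.random_pd_prob < 1:
            raise ValueError("random_pd_prob must be in [0, 1)")
        if self.post_progression not in ("null", "linked"):
            raise ValueError("post_progression must be 'null' or 'linked'")
        if self.scan_jitter < 0 or self.scan_jitter >= self.scan_interval / 2:
            raise ValueError("scan_jitter must be in [0, scan_interval/2)")


def docetaxel_like(**overrides) -> CohortSpec:
    """Second-line docetaxel comparator arm (8-weekly scans)."""
    return replace(CohortSpec(), **overrides)


def erlotinib_like(**overrides) -> CohortSpec:
    """Second-line erlotinib comparator arm: 6-weekly scans, slightly
    smaller tumours, early net growth, short follow-up (OS median not
    reached)."""
    spec = CohortSpec(
        n_patients=369,
        scan_interval=6.0,
        max_followup=72.0,
        mu=(math.log(8.0), math.log(0.035), math.log(0.035)),
        omega2=(0.45, 0.20, 0.30),
        pp_rate=_LN2 / 26.0,
        censoring_time=48.0,
    )
    return replace(spec, **overrides)


def paclitaxel_carboplatin_like(**overrides) -> CohortSpec:
    """First-line paclitaxel/carboplatin arm: larger tumours, deeper
    response, longer PFS."""
    spec = CohortSpec(
        n_patients=413,
        scan_interval=8.0,
        max_followup=104.0,
        mu=(math.log(10.7), math.log(0.065), math.log(0.028)),
        omega2=(0.40, 0.20, 0.30),
        pp_rate=_LN2 / 17.8,  # median OS - PFS ~= 4.1 months
        censoring_time=130.0,
    )
    return replace(spec, **overrides)


def apply_progression(sld, threshold: float) -> Optional[int]:
    """Index of the first scan with SLD >= (1 + threshold) x running nadir.

    The nadir is the smallest SLD seen *before* the scan under test (the
    baseline counts).  Returns ``None`` when no scan qualifies.  A zero
    threshold degenerates to the first non-decrease from the nadir.
    """
    sld = np.asarray(sld, dtype=float)
    if sld.size == 0:
        raise ValueError("empty series")
    nadir = sld[0]
    for i in range(1, sld.size):
        if sld[i] >= (1.0 + threshold) * nadir:
            return i
        nadir = min(nadir, sld[i])
    return None


def generate_cohort(
    spec: CohortSpec,
    seed: Optional[int] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one trial arm.

    Returns ``(assessments, survival, params_true)``:

    * ``assessments`` — long format ``patient_id, time_weeks, sld_cm``,
      truncated at progression (or death during imaging);
    * ``survival`` — one row per patient: ``patient_id, pfs_weeks,
      pfs_event, os_weeks, os_event, progression_is_death``;
    * ``params_true`` — the generating parameters and derived true metrics
      (``A, B, C, DR, GR, TTG, span``) for recovery tests.

    ``seed`` overrides ``spec.seed``; all randomness flows through one
    ``numpy`` generator, so outputs are reproducible under a fixed seed.
    """
    spec.validate()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)

    mu = np.asarray(spec.mu, dtype=float)
    omega = np.sqrt(np.asarray(spec.omega2, dtype=float))

    # the administrative cut-off is a calendar cut: no imaging beyond it
    horizon = min(spec.max_followup, spec.censoring_time)
    n_scans = int(math.floor(horizon / spec.scan_interval)) + 1
    base_grid = np.arange(n_scans) * spec.scan_interval

    a_rows, s_rows, p_rows = [], [], []
    width = len(str(spec.n_patients))
    for i in range(spec.n_patients):
        pid = f"P{i + 1:0{width}d}"
        theta = mu + omega * rng.standard_normal(3)
        params = KineticParams(*np.exp(theta))

        times = base_grid.copy()
        if spec.scan_jitter > 0:
            times[1:] = times[1:] + rng.uniform(
                -spec.scan_jitter, spec.scan_jitter, size=n_scans - 1
            )
        truth = sld_at(params, times)
        observed = truth + rng.normal(0.0, spec.sigma, size=n_scans)
        observed = np.maximum(observed, spec.sld_floor)

        pd_idx = apply_progression(observed, spec.progression_threshold)
        if spec.random_pd_prob > 0:
            extra = rng.random(n_scans) < spec.random_pd_prob
            extra[0] = False
            hit = np.flatnonzero(extra)
            if hit.size and (pd_idx is None or hit[0] < pd_idx):
                pd_idx = int(hit[0])

        # death during imaging: first interval (between consecutive scans)
        # in which an independent Bernoulli fires
        death_time = math.inf
        if spec.death_during_imaging_prob > 0:
            fires = rng.random(n_scans - 1) < spec.death_during_imaging_prob
            k = np.flatnonzero(fires)
            if k.size:
                k0 = int(k[0])
                death_time = float(
                    times[k0] + rng.uniform(0.0, times[k0 + 1] - times[k0])
                )

        pd_time = math.inf if pd_idx is None else float(times[pd_idx])
        progression_is_death = 0
        if death_time < pd_time:
            # death before any radiological progression: PFS event is death
            last_idx = int(np.searchsorted(times, death_time, side="right") - 1)
            pfs_weeks, pfs_event = death_time, 1
            os_weeks, os_event = death_time, 1
            progression_is_death = 1
        elif pd_idx is not None:
            last_idx = pd_idx
            pfs_weeks, pfs_event = pd_time, 1
            os_weeks, os_event = _overall_survival(
                spec, params, pd_time, times, pd_idx, rng
            )
        else:
            last_idx = n_scans - 1
            pfs_weeks, pfs_event = float(times[-1]), 0
            os_weeks, os_event = _overall_survival(
                spec, params, float(times[-1]), times, last_idx, rng
            )

        kept = slice(0, last_idx + 1)
        for t, y in zip(times[kept], observed[kept]):
            a_rows.append((pid, float(t), float(y)))
        s_rows.append(
            (pid, float(pfs_weeks), int(pfs_event), float(os_weeks), int(os_event),
             int(progression_is_death))
        )
        span = float(times[last_idx] - times[0])
        tp = turning_point(params)
        ttg_true = min(max(tp, 0.0), span) if span > 0 else 0.0
        p_rows.append(
            (pid, params.A, params.B, params.C, params.B, params.C, ttg_true, span)
        )

    assessments = pd.DataFrame(a_rows, columns=["patient_id", "time_weeks", "sld_cm"])
    survival = pd.DataFrame(
        s_rows,
        columns=[
            "patient_id", "pfs_weeks", "pfs_event", "os_weeks", "os_event",
            "progression_is_death",
        ],
    )
    params_true = pd.DataFrame(
        p_rows, columns=["patient_id", "A", "B", "C", "DR", "GR", "TTG", "span"]
    )
    return assessments, survival, params_true


def _overall_survival(spec, params, from_time, times, idx, rng):
    """Draw OS for a patient alive at ``from_time`` (progression or end of
    imaging) and apply administrative censoring."""
    rate = spec.pp_rate
    if spec.post_progression == "linked":
        span = float(times[idx] - times[0])
        tp = turning_point(params)
        ttg = min(max(tp, 0.0), span) if span > 0 else 0.0
        rate = rate * math.exp(spec.gamma_gr * params.C + spec.gamma_ttg * ttg)
    os_weeks = from_time + rng.exponential(1.0 / rate)
    if os_weeks > spec.censoring_time:
        return float(spec.censoring_time), 0
    return float(os_weeks), 1
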