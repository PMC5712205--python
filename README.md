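# tgikit

Tumour-growth-inhibition kinetics and survival in NSCLC trial arms.

A recurring question in oncology drug development is whether metrics derived
from models of tumour-size dynamics — the re-growth rate (GR) and the time to
tumour re-growth (TTG) — predict survival better than empirical endpoints
such as progression-free survival (PFS).  `tgikit` implements that analysis
end to end for longitudinal RECIST sum-of-longest-diameters (SLD) data:

* **Kinetic model** — the biexponential law
  `SLD(t) = A·(e^{−B·t} + e^{C·t} − 1)` with nadir at
  `tp = (ln B − ln C)/(B + C)`; in forward time B = decay rate (DR),
  C = re-growth rate (GR), tp = TTG.
* **Population fit** — nonlinear mixed-effects estimation with log-normal
  inter-individual variability and additive residual error (iterated
  two-stage penalised scheme with Laplace corrections), returning empirical
  Bayes parameters per patient.
* **Forward vs reverse alignment** — series indexed from treatment start
  (outcome: overall survival, OS) or reflected about the progression scan
  (outcome: OS − PFS).  Reverse alignment removes the guarantee-time bias of
  TTG/GR: the time spent *estimating* a metric can no longer count toward
  the outcome.
* **Individual risk** — signed Gönen–Heller-style concordance probability
  (CP) from a Cox fit, with 95% percentile-bootstrap intervals (1,000
  patient resamples); CP = 0.5 means no consistent relationship, and a
  metric is significant when its interval excludes 0.5.
* **Group risk** — 1,000 resampled head-to-head test trials (default arm
  sizes 110/112) giving predictive distributions of the PFS hazard ratio and
  of the oriented GR / TTG mean ratios, plus the r² between the two ratios.
* **Synthetic cohorts** — generator emulating phase III NSCLC comparator
  arms (scheduled scans, measurement noise, RECIST-like 20%-over-nadir
  progression with imaging stopping at progression, a small
  progression-by-death fraction, configurable post-progression survival), so
  the whole pipeline is testable without any external data.

See `docs/methods.md` for the model, the estimation scheme, calibration of
the synthetic arms, and known limitations (including why reverse-time rate
recovery is structurally approximate and why the null post-progression
model caps forward CPs near 0.60).

## Worked example

```python
import numpy as np
from tgikit import (docetaxel_like, generate_cohort, fit_and_derive,
                    individual_risk, progressor_assessments, simulate_test_trials)

# a synthetic docetaxel-like comparator arm, 200 patients
assessments, survival, truth = generate_cohort(docetaxel_like(n_patients=200), seed=42)

# population fit in forward time, then concordance of GR and TTG with OS
pop, metrics = fit_and_derive(assessments, alignment="forward")
print("population exp(mu) [A,B,C]:", np.round(np.exp(pop.mu), 4), " sigma:", round(pop.sigma, 3))
print(individual_risk(metrics, survival, "forward", n_boot=1000, seed=42)
      [["metric", "cp", "ci_low", "ci_high", "significant"]].round(3))

# reverse alignment: refit on progression-anchored series, outcome OS - PFS
_, met_r = fit_and_derive(progressor_assessments(assessments, survival), "reverse")
print(individual_risk(met_r, survival, "reverse", n_boot=1000, seed=43)
      [["metric", "cp", "ci_low", "ci_high", "significant"]].round(3))
```

Output:

```
population exp(mu) [A,B,C]: [8.4181 0.0502 0.034 ]  sigma: 0.303
metric    cp  ci_low  ci_high  significant
    GR 0.552   0.517    0.594         True
   TTG 0.563   0.536    0.597         True
metric    cp  ci_low  ci_high  significant
    GR 0.491   0.457    0.525        False
   TTG 0.467   0.431    0.507        False
```

The fitted population parameters sit close to the generating values
(baseline ≈ 8.4 cm, rates ≈ 0.05 and 0.03 per week, residual SD ≈ 0.3 cm).
Forward-aligned GR and TTG correlate significantly with OS (CPs ≈ 0.55–0.56,
intervals excluding 0.5) — but only because the time taken to measure them
is part of the outcome.  After reverse alignment the CPs collapse onto 0.5
and lose significance: under this cohort's null post-progression model,
pre-progression dynamics carry no information about survival after
progression, and the analysis correctly says so.

A group-risk run against a second, independently generated arm:

```python
res = simulate_test_trials(arm_test, arm_reference, 110, 112, replicates=1000, seed=7)
print(res.summary().round(3)); print("r2:", round(res.r2_ttg_gr, 3))
```

```
   metric  median  pi_low  pi_high  n_replicates
   pfs_hr   0.982   0.748    1.281          1000
 gr_ratio   1.050   0.848    1.303          1000
ttg_ratio   1.034   0.716    1.514          1000
r2: 0.318
```

Two arms drawn from the same population: all three outcome distributions
centre on 1 (no treatment difference), and the TTG and GR ratios correlate
only weakly (r² ≈ 0.32) — the two metrics carry substantially different
information, so the choice between them can change a go/no-go prediction.

## Command line

```bash
tgikit simulate --seed 1 --arm docetaxel --out-dir cohort/
tgikit fit --assessments cohort/assessments.csv --out-dir fit/
tgikit concordance --assessments cohort/assessments.csv --survival cohort/survival.csv \
       --alignment reverse --n-boot 1000 --seed 1
tgikit trialsim --test armA.csv --reference armB.csv --replicates 1000 --seed 1
tgikit summarize --assessments cohort/assessments.csv --survival cohort/survival.csv
```

File formats: `assessments.csv` (`patient_id,time_weeks,sld_cm`),
`survival.csv` (`patient_id,pfs_weeks,pfs_event,os_weeks,os_event[,progression_is_death]`).
All outputs carry a `#`-comment provenance header (version, seed, config
hash) which the readers skip.

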