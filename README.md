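# phjoint

Joint models of longitudinal biomarkers and time to kidney failure for
primary hyperoxaluria type 1 (PH1) registry-style cohorts — and the
last-observation-carried-forward (LOCF) time-dependent Cox comparator they
are meant to replace.

## The problem

PH1 is a rare genetic disorder of hepatic oxalate overproduction. Excess
oxalate must be excreted by the kidneys, so urinary oxalate (UOX) reflects
production, plasma oxalate (POX) rises as kidney function is lost, and eGFR
tracks that loss. Registry patients are followed from diagnosis until
kidney failure (transplant, dialysis, or eGFR < 15 ml/min/1.73 m²), with
POX, UOX and eGFR measured sparsely, asynchronously, and on clinical
indication rather than by design. Two analyses of such data are provided:

* **LOCF time-dependent Cox regression** (`phjoint.locf_cox`): each
  biomarker enters the proportional-hazards model as a step function,
  holding its last observed log value until the next measurement, on a
  counting-process `(start, stop]` table with delayed entry. Subjects
  without at least one measurement of every biomarker before their event
  are excluded.
* **Multivariate Bayesian joint models** (`phjoint.joint_model`): for
  biomarker k of subject i,

      log y_ik(t) = m_ik(t) + ε,   m_ik(t) = x_ik(t)'β_k + b_ik,
      h_i(t) = h0(t) · exp( γ'w_i + Σ_k α_k · m_ik(t) ),

  where x_ik(t) holds age at diagnosis, sex, and a natural cubic spline in
  years since diagnosis; b_i ~ N_K(0, D) are random intercepts correlated
  across biomarkers; and the hazard depends on the subject-specific
  *predicted* current biomarker value — a smooth curve, not a stale step
  function. Hazard ratios are reported per doubling of the biomarker as
  2^α with 95% credible intervals, and the cross-biomarker correlations of
  D are estimated as part of the model. Subjects may contribute with as few
  as one (or zero) measurements of a biomarker.

Because no PH1 registry data are publicly deposited, the package includes a
synthetic registry generator (`phjoint.synthetic_cohort`) with known ground
truth: smooth correlated latent trajectories, gamma-renewal visit
processes, site-level assay availability, administrative censoring, and
event times drawn by inverse transform from the joint-model hazard — so
every estimator here can be validated by parameter recovery. Multiple
imputation of missing baseline values with Rubin's-rules pooling
(`phjoint.mi_pooling`) and an end-to-end pipeline with publication-style
tables (`phjoint.report`, CLI `phjoint`) round out the toolkit.

## Worked example

```python
from phjoint.synthetic_cohort import default_config, simulate_cohort
from phjoint.data_model import apply_inclusion
from phjoint.report import summarize_cohort
from phjoint.locf_cox import build_counting_process, fit_cox_td
from phjoint.joint_model import (JointModelSpec, fit_joint,
                                 hazard_ratio_per_doubling,
                                 random_effect_correlations)
from phjoint.scenarios import ANALYSIS_SPLINES

subjects, observations, truth = simulate_cohort(default_config(), seed=70003)
subjects, observations, log = apply_inclusion(subjects, observations)

table, excl = build_counting_process(subjects, observations, ["POX", "UOX", "eGFR"])
cox = fit_cox_td(table, ["log_POX", "log_UOX", "log_eGFR", "age_at_dx", "sex_male"])

spec = JointModelSpec(
    biomarkers={bm: ANALYSIS_SPLINES[bm] for bm in ("POX", "UOX", "eGFR")},
    chains=2, warmup=600, draws=800)
jfit = fit_joint(subjects, observations, spec, seed=80003,
                 enforce_convergence=False)
```

This prints (cohort: n = 166, 53 kidney-failure events, median 5 [4, 8]
eGFR measures per subject; the generating truth is HR/doubling 1.87 for
POX, 0.44 for UOX, 0.35 for eGFR):

```
LOCF time-dependent Cox (HR per doubling):      93 subjects, 21 events
           hr_per_doubling  hr_lo  hr_hi      p
log_POX              0.875  0.447  1.714  0.697
log_UOX              0.898  0.496  1.624  0.721
log_eGFR             0.837  0.367  1.907  0.672

Multivariate joint model (HR per doubling):     166 subjects, 53 events
  POX:  1.76 [0.82, 5.49]
  UOX:  0.44 [0.16, 0.91]
  eGFR: 0.41 [0.25, 0.96]

Random-intercept correlations:
    pair  mean    lo    hi
 POX-UOX  0.67  0.52  0.79
POX-eGFR -0.70 -0.80 -0.57
UOX-eGFR -0.52 -0.64 -0.38
```

The contrast is the package's central point: the LOCF Cox model loses 73
subjects and 32 events to its complete-biomarker requirement and its stale
step-function covariates attenuate every association to the null, while
the joint model uses all subjects, recovers the generating hazard ratios
(including the *protective* direction of UOX after adjusting for POX and
eGFR, which reflects reduced renal oxalate excretion as kidney function
declines), and estimates the cross-biomarker correlations.

The same analyses run from the shell:

```sh
phjoint simulate --n 166 --seed 70003 --out cohort/
phjoint fit-locf  --subjects cohort/subjects.csv --observations cohort/observations.csv --out locf/
phjoint fit-joint --subjects cohort/subjects.csv --observations cohort/observations.csv --seed 80003 --out joint/
phjoint report    --seed 70003 --out report/      # full pipeline + plots
```

## Input formats

Two CSV files. Subjects: `subject_id, age_at_dx, sex {female,male},
entry_time, event_time, event {kidney_failure,censored}`, times in decimal
years since PH1 diagnosis. Observations (long format): `subject_id,
biomarker {POX,UOX,eGFR}, time, value`, values strictly positive
(models work on the natural-log scale); observation times from one year
before diagnosis are accepted. `phjoint.data_model` also derives the
composite endpoint from raw transplant/dialysis/eGFR records and computes
eGFR from serum creatinine via the full-age-spectrum (FAS) equation.

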