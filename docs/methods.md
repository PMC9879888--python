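# Methods

## Data model and time scale

All times are decimal years since PH1 diagnosis. A subject is at risk on
`(entry_time, event_time]` (delayed entry / left truncation); the composite
kidney-failure endpoint is the first of transplant, dialysis initiation, or
an eGFR measure strictly below 15 ml/min/1.73 m². Death is treated as
censoring; competing-risk and multistate extensions are out of scope.
Cohort inclusion requires age ≥ 2 years at diagnosis, freedom from kidney
failure at diagnosis, and at least one eGFR measure between one year before
diagnosis and the event; pre-diagnosis observations (time ≥ −1) enter the
longitudinal submodels as ordinary data points.

eGFR can be derived from serum creatinine with the full-age-spectrum (FAS)
equation, 107.3 / (Scr/Q), attenuated by 0.988^(age−40) above age 40,
where Q is the age/sex median serum creatinine. The bundled Q table uses
the standard adult medians (0.90 mg/dL men, 0.70 women) and per-year
pediatric values; it is a transcription, and users with calibrated local Q
values should pass their own `q_table`.

## Longitudinal submodels

Each biomarker is modeled on the natural-log scale (positivity is enforced
at parse time) with fixed effects for age at diagnosis, sex (female
reference), and a natural cubic spline in time, plus a subject random
intercept. The spline basis is the standard construction — cubic B-splines
with zero second derivative at and beyond the boundary knots — and matches
R's `splines::ns` element-wise (a frozen R oracle pins this in the tests).
Values outside the boundary knots extrapolate linearly, with a warning in
user-facing paths. Internal knots sit at percentiles of the pooled
observation times using linear-interpolation (type-7) quantiles; the
percentile convention is pinned because knot reproducibility matters more
than the particular choice. The default functional forms are df = 2
(internal knot at the median) for POX and eGFR and df = 5 (knots at the
20/40/60/80th percentiles) for UOX; `select_spline_spec` compares candidate
forms by an information criterion at the mixed-model stage, with DIC
comparisons available at the joint-model stage.

The maximum-likelihood fit profiles out everything except the variance
ratio d/σ², which is optimized by bounded scalar search; this makes the fit
deterministic and handles the d = 0 boundary (e.g. one subject) gracefully.
Random slopes are not implemented; the longitudinal design reserves space
for them but registry-scale data rarely support them.

## The multivariate joint model

The K log-biomarker processes and the kidney-failure hazard are linked by
correlated random intercepts b_i ~ N_K(0, D):

    h_i(t) = h0(t) · exp( γ_age·age_i + γ_sex·male_i + Σ_k α_k m_ik(t) ),
    m_ik(t) = x_ik(t)'β_k + b_ik.

The association structure is the current predicted value m_ik(t); lagged
or cumulative (AUC) structures are deliberate extension points, not
implemented. The baseline hazard is piecewise constant on (by default) 7
intervals whose edges are event-time quantiles — transparent, conjugate,
and flexible enough to absorb the population time trend. The cumulative
hazard over each subject's at-risk window is computed by Gauss–Legendre
quadrature (7 nodes per baseline interval, so the integrand is smooth
within each panel); a generic `cumulative_hazard` routine with a
configurable node count is exposed and verified against closed forms.

Priors: N(0, 10²) on all regression coefficients (β, γ, α, on the log
scale), half-normal(5) on residual SDs, Gamma(0.01, 0.01) on baseline
hazard levels, and inverse-Wishart(K+2, I) on D. The inverse-Wishart was
chosen over a separated LKJ-type prior because it gives D a closed-form
Gibbs update, which is what keeps full-cohort fits in the tens of seconds
on one CPU; at the cohort sizes of interest the prior is dominated by the
likelihood (n ≥ 150 subjects against K+2 prior degrees of freedom).

### Sampler

Estimation is Metropolis-within-Gibbs with carefully chosen blocks:

* **Random intercepts b_i** — independence Metropolis from the exact
  Gaussian conditional given the longitudinal data and N(0, D) prior. The
  longitudinal and prior factors cancel in the acceptance ratio, leaving
  only the survival factor; because b_i is time-constant, the subject's
  cumulative hazard is `base_i · exp(α·b_i)` with `base_i` precomputed, so
  the whole field updates vectorized with near-unit acceptance and
  decorrelates in one sweep.
* **β_k** — independence proposal from the Gaussian longitudinal
  conditional, Metropolis-corrected by the survival factor (exact Gibbs
  when α_k = 0).
* **σ_k** — adaptive random-walk on log σ.
* **D** — conjugate inverse-Wishart Gibbs draw.
* **Baseline levels λ_j** — conjugate gamma Gibbs draws (events and
  hazard-weighted exposure per interval).
* **(γ, α)** — adaptive random-walk Metropolis (Haario-style running
  covariance × an acceptance-adapted scale, both frozen after warmup),
  several sub-steps per sweep.
* **Trend-swap move** — when a biomarker's population curve trends in
  time, α_k trades off against the flexible baseline (the hazard shape can
  absorb an α change), creating a slow posterior ridge. An extra
  Metropolis move proposes α_k → α_k + ε together with the compensating
  tilt log λ_j → log λ_j − ε·m̄_k(j), where m̄_k(j) is the time-weighted
  (hazard-independent, hence symmetric) mean predicted value in interval j;
  the multiplicative Jacobian is included. This move raised the effective
  sample size of the association coefficients by an order of magnitude.

Chains (≥ 2 by contract) are initialized from the per-biomarker mixed-model
fits, their empirical-Bayes intercepts, and an LOCF Cox fit for (γ, α);
each chain consumes an independent stream spawned from the user's seed.
Split-chain R-hat and bulk ESS (via arviz) are computed for every reported
parameter; by default a fit fails loudly (`ConvergenceError`, carrying the
diagnostics and the partial draws) if any R-hat exceeds 1.05 or any ESS
falls below 400. The default 2 × (1000 warmup + 2500 kept) draws clears
these gates on registry-scale problems in about a minute; validation
studies in the test suite run shorter chains with the gate disabled and
assert recovery instead.

### Reporting

Hazard ratios are computed draw-wise as 2^β (per doubling of the
biomarker), summarized by the posterior median and equal-tailed 95%
interval. Random-effect correlations are computed draw-wise from D; a
positive correlation means subjects persistently high on one biomarker
tend to be persistently high on the other after fixed effects. Model fit
is the conditional-deviance DIC, D̄ + pD with pD = D̄ − D(posterior mean),
where the deviance conditions on the random effects (longitudinal +
survival likelihood given b) and posterior means plug in for both θ and b
— the usual choice for shared-random-effect joint models. Significance
annotation in report tables uses two-sided 0.05 without multiplicity
adjustment.

## LOCF counting-process comparator

For a biomarker set, follow-up begins at the first time every requested
biomarker has been observed (left truncation); subjects never attaining
all of them before the event are excluded and logged. Rows are half-open
`(start, stop]`, a new row at each measurement time, covariates constant
within rows; a measurement exactly at the event time does not update the
covariate for the event row (predictors must be known just before the
event). Duplicate same-time measurements resolve last-wins with a warning.
The partial likelihood is maximized by damped Newton with Efron tie
handling by default (Breslow by flag); covariates are centered internally
(the partial likelihood is location-invariant) to guard the exponentials.
Monotone likelihoods (separation) are flagged, not fatal. Schoenfeld
residuals use the tie-method-consistent risk-set means, so they sum to
exactly zero at the MLE, and a residual-versus-time plot with a lowess
smooth is provided as the proportional-hazards diagnostic. The CKD-3a
sensitivity subset moves each subject's entry to their first eGFR < 60
observation (subjects never below 60 are dropped); values observed before
the new entry remain eligible as carried-forward values at entry.

## Multiple imputation

The main analyses are complete-case, on the premise that missing oxalate
assays reflect site availability rather than patient characteristics.
The sensitivity path imputes *baseline* log-biomarkers only (the earliest
observation in a window around diagnosis; the pipeline uses ±3 years to
respect registry sparsity): a joint normal model over (baseline
log-biomarkers, age, sex) is estimated from complete cases, and each of
the M imputations draws parameters from the normal-inverse-Wishart
posterior before drawing missing values from the implied conditional
normals — proper MI, so Rubin's rules apply. Pooling is on the log-HR
scale (Q̄, W̄, B, T = W̄ + (1+1/M)B, classical degrees of freedom), with
2^β applied at the end.

## Synthetic registry cohorts

`default_config()` encodes the study conditions the generator emulates:
166 subjects; age at diagnosis 2 + Gamma(1.6, 8) years; half male;
administrative censoring N(16.3, 1.4) years; latent log-scale curves with
eGFR declining from ~85 toward ~25 ml/min/1.73 m² over 20 years, POX
rising as clearance is lost, UOX drifting down late; residual SDs
0.30/0.35/0.25 (POX/UOX/eGFR); random-intercept SDs 0.45/0.40/0.35 with
correlations +0.59 (POX–UOX), −0.76 (POX–eGFR), −0.38 (UOX–eGFR); gamma
renewal visits with mean gaps 6 y (POX) and 3 y (UOX, eGFR), eGFR
guaranteed at baseline; assay availability 111/166 (POX), 150/166 (UOX),
1.0 (eGFR); associations α = (+0.9, −1.2, −1.5) per natural-log unit; and
a constant baseline hazard set by a documented one-dimensional calibration
search (`calibrate_baseline_hazard`, bundled level 1.5645 per person-year
at the reference predictor) targeting a 36.2% event fraction.
Under these defaults a generated cohort shows ~36% events, median ~5–6
eGFR/UOX and ~2–3 POX measures per subject, and ~14 years mean follow-up
(administrative censoring minus early events).

Event times use inverse-transform sampling: because the random intercepts
are time-constant, the hazard factorizes into a shared time curve and a
per-subject scale, so one shared cumulative-hazard curve (composite
Gauss–Legendre, panels never straddling a baseline break) is inverted per
subject by bracketing and Brent refinement to ~1e−12. A generic
`simulate_event_time` for arbitrary log-predictors is exposed and verified
against closed forms. An optional switch couples the visit rate to low
latent eGFR (informative observation); it is off by default because the
fitted models assume non-informative visits — the switch exists to study
that assumption's violation, not to represent the default conditions.

What the generator does **not** emulate: measurement-batch effects, assay
detection limits, informative dropout, death as a competing risk, random
slopes or serial within-subject correlation, and treatment changes over
follow-up. Passing parameter-recovery tests therefore demonstrates
correctness of the estimation machinery under the stated model, not
robustness to these real-data features.

## Validation studies and their design

* **Association recovery**: two biomarkers, n = 300, α = (0.7, −0.5),
  random-intercept correlation 0.5 — posterior means land within 3
  posterior SDs of truth, and 95% intervals over 20 replicate cohorts
  (n = 150, shortened chains) cover truth at a rate consistent with
  nominal (binomial test at 0.01).
* **Correlation recovery**: the three-biomarker default curves with full
  availability and ~2.5-year visit gaps at n = 500 recover the configured
  correlations (+0.59, −0.76, −0.38) within 3 posterior SDs.
* **LOCF bias contrast**: sparse asynchronous noisy visits with a negative
  UOX-type association (α = (0.7, −0.7), correlation 0.5, n = 300). A
  150-replicate oracle fixes the LOCF attenuation: the Cox estimate of the
  UOX coefficient centers at −0.234 (SD 0.168) against a truth of −0.7 —
  two-thirds of the association is lost — while the joint model's interval
  covers the truth. A stronger design (α = −1.0, correlation 0.7,
  n = 200) was rejected after an oracle MLE using the *true* latent curves
  showed the association is too weakly identified there for any method;
  the retained conditions are the strongest contrast that remains
  identifiable at this cohort size.
* **Factorization**: with α pinned at 0 the posterior factorizes — survival
  coefficients match a standalone profile-likelihood piecewise-exponential
  PH fit, and longitudinal posteriors match the standalone mixed-model
  MLEs.
* **Closed-form oracles**: Cox grid search and null partial likelihood,
  Gauss–Legendre versus analytic cumulative hazards, the random-intercept
  shrinkage formula, Rubin's rules on a hand example, Schoenfeld zero-sum,
  and the natural-spline boundary constraints.

Simulation sizes in the shipped tests (n = 150–500, 2 chains of a few
hundred to a couple thousand draws) are the package's own choice of a
few-minute validation budget; the same studies rerun at larger sizes by
changing one argument.

## Numerical choices and edge cases

Quantiles are linear-interpolation (type-7) everywhere. Ties in the
composite endpoint collapse to one event at that time. Subjects with no
observations of a biomarker get the prior-mean random intercept (flagged)
in empirical-Bayes prediction and are sampled from their survival-informed
conditional in the joint model. Non-positive-definite D proposals score
−∞ rather than raising. The Cox fitter reports estimates at the iteration
cap with a warning under monotone likelihoods. Event-time inversion
returns +∞ (administratively censored) when the cumulative hazard over
the horizon cannot reach the target. All randomness flows from a single
root seed through named independent streams (covariates, random effects,
visits, noise, events, censoring), so any one component can be varied
without perturbing the others and identical (config, seed) pairs
reproduce cohorts bit for bit.
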