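# Methods

## The kinetic GFR estimator

A single serum creatinine (sCr) or plasma cystatin C (pCysC)
measurement estimates GFR only at steady state, when production and
renal excretion of the marker balance. In the hours after kidney
transplantation neither holds: a recovering graft pulls concentrations
down from their dialysis-dependent starting level, a failing graft
lets them climb. The kinetic estimator reconciles the level of a
marker with its rate of change under a one-compartment mass balance,

```
KeGFR = (Bc × eGFR) / MeanBc × (1 − 24·ΔBc / (Δt · MaxΔBc/d))
```

with

- `Bc × eGFR` — the anchor concentration times its steady-state
  CKD-EPI eGFR. Multiplied by 1.44 (1440 min/day ÷ 1000 mL/L) this is
  the estimated daily marker production (μmol/d/1.73 m² or
  mg/d/1.73 m²); it is computed once per subject, from the 4 h sample
  by default, and shared by every interval.
- `MeanBc`, `ΔBc`, `Δt` — the mean and difference (later − earlier) of
  two consecutive concentrations and their spacing in hours. Each
  consecutive pair yields one estimate, labelled by the later
  timepoint; it approximates the average GFR over the interval.
- `MaxΔBc/d` — the maximal theoretical one-day rise of the marker at
  zero GFR: daily production divided by the distribution volume
  Vd = 0.6 L/kg × weight for creatinine (total body water) or
  0.2 L/kg × weight for cystatin C (extracellular fluid).

**Sign convention.** ΔBc is later − earlier, so a rising marker shrinks
the bracket and a marker rising at the full anuric rate
(ΔBc/Δt = MaxΔBc/d per day) zeroes it. This is the only convention
under which both limits hold: a flat series returns the anchor eGFR
exactly (the anchor concentration cancels against MeanBc), and an
anuric accumulation returns exactly zero.

**Clamping.** Assay noise or an underestimated MaxΔBc/d can push the
bracket below zero; since a negative filtration rate is not physical,
estimates are clamped to 0 by default. The pre-clamp value is always
retained in the returned `KineticEstimate` and the count of clamped
values is logged — it is a useful diagnostic of production
misestimation.

**Production variants.** The daily-production term is the weakest link
and is configurable: CKD-EPI back-calculation (reference),
Cockcroft-Gault clearance (creatinine only, absolute mL/min), a fixed
anuric maximum (235 μmol/L/d for creatinine, 3 mg/L/d for cystatin C —
`fixed_max_delta` bypasses production entirely and keeps the CKD-EPI
numerator), a configurable constant per 1.73 m² scaled by BSA/1.73
(`sjostrom`, for cystatin C production models published as population
constants; it has no default and must be set explicitly), and a
verbatim amount/day (`fixed_production`, the testing hook that lets
simulations supply ground truth). Output is indexed per 1.73 m² by
default; `absolute_ml_min` multiplies by DuBois BSA/1.73 and requires
height.

Note that 3 mg/dL/d of creatinine is 265.2 μmol/L/d, not 235; where
the two appear together in the clinical literature the SI value is the
one used here.

**Discretisation error.** The formula treats the marker's trajectory as
linear within each interval while the true one-compartment solution is
exponential; the estimator therefore recovers a constant GFR g with
relative error that scales as (ĝΔt/Vd)²/12. At the study's 4 h spacing
this is < 1% for g ≤ 60 mL/min with Vd = 42 L, and it shrinks
monotonically with Δt — both asserted by tests.

## Steady-state comparators

CKD-EPI 2009 (creatinine) and CKD-EPI 2012 (cystatin C only) in their
published piecewise power-law forms; Cockcroft-Gault for absolute
creatinine clearance; DuBois BSA = 0.007184·W^0.425·H^0.725.
Creatinine is carried in μmol/L everywhere and converted to mg/dL
(factor 88.4) only inside the equations. The race coefficient is an
explicit boolean defaulting to false. Cockcroft-Gault clamps at zero
for age ≥ 140 rather than returning a negative clearance. Missing
weight/height raise rather than impute.

## Evaluation statistics

- **AUC** is the midrank Mann-Whitney statistic; direction is always an
  explicit argument (`lower_predicts_event` for GFR-type predictors,
  `higher_predicts_event` for raw concentrations), never inferred.
- **DeLong** placement-value covariance gives single-AUC CIs and the
  paired two-predictor test (normal approximation, two-sided). The
  implementation agrees with pROC's to 7 decimals on shared fixtures.
  At n ≈ 60 the asymptotic test is mildly liberal (empirical size
  ≈ 0.057 at α = 0.05 under an independent-noise null, measured at
  20 000 replicates) — a finite-sample property of the method itself,
  shared by standard implementations.
- **Youden cutoffs** scan all n+1 threshold positions; ties break
  toward higher sensitivity; the reported cutoff is the midpoint
  between the adjacent distinct scores. Cutoff tables report the
  points nearest 90% sensitivity, Youden-optimal, and nearest 90%
  specificity, with PPV/NPV at observed prevalence.
- **Base-model augmentation** refits the clinical risk score as a
  logit(base_risk) covariate (in-sample recalibration, the default) or
  carries it as a fixed offset; the biomarker enters as a second
  covariate. Fits use an exact-gradient L-BFGS maximum-likelihood
  optimiser (agreeing with statsmodels' MLE to 1e-5); quasi-separated
  fits are retried with a ridge penalty of 1e-3 on non-intercept
  coefficients and a logged warning, so extreme synthetic cohorts
  degrade gracefully instead of crashing.
- **IDI** components are the direct means (risk increase among events,
  decrease among non-events); their sum equals the discrimination-slope
  difference, asserted to 1e-12. CIs come from a seeded subject-level
  bootstrap (default 2000 resamples) that refits both models inside
  each resample; the analytic paired-t (Pencina) SE is available as an
  option. Resampling always requires an explicit seed.
- **Censoring**: dialysis resets marker levels, so subjects are removed
  from analysis at and after the timepoint their dialysis began;
  earlier timepoints keep them, outcome label included. The operation
  is idempotent.
- **Bland-Altman** bias and 1.96·SD limits; **Spearman** via midranks
  with the t-approximation p-value.

## Synthetic cohort generator

No patient-level dataset of this design is publicly deposited, so the
pipeline runs on simulated cohorts drawn from the same model the
estimator assumes:

- **Kinetics.** Each subject's marker follows the closed-form solution
  of Vd·dB/dt = P − ĝB with constant latent GFR (ĝ = 1.44·g L/day),
  from a dialysis-dependent starting concentration (sCr ≈ 700 ± 150
  μmol/L, pCysC ≈ 5.5 ± 1.0 mg/L — typical ESRD levels). Observed
  concentrations are multiplied by lognormal noise at CV 3%, a typical
  analytic coefficient of variation for these assays.
- **Classes.** DGF subjects draw a persistently low GFR (uniform 0–8
  mL/min), non-DGF subjects a recovering one (uniform 20–60 mL/min;
  optionally ramping from 50% to 100% over 12 h). Prevalence defaults
  to 22/56.
- **Production.** Creatinine 150 ± 25 μmol/kg/day (≈ 10.5 mmol/day at
  70 kg, standard adult excretion); cystatin C 110 ± 20 mg/day
  (consistent with ~1 mg/L steady state at normal GFR). Vd
  coefficients 0.6/0.2 L/kg.
- **Clinical base risk** is binormal in the latent class with
  separation √2·Φ⁻¹(AUC_target), AUC target 0.70, mapped through a
  logistic link centred at the prevalence. Calibration is exact in
  expectation; in-sample AUC varies with n by ordinary sampling error.
- **Dialysis** is assigned to DGF subjects only (the outcome is defined
  as dialysis within 168 h): by default 4/22 of them between 4 h and
  8 h (so censoring is exercised mid-study), the rest between 12 h and
  one week. Samples at or after dialysis are absent from the
  measurements file.
- **12-month eGFR** is latent-GFR signal plus noise
  (25 + 0.7·g + N(0,10), floored at 5), giving the positive rank
  correlation with early kinetic estimates that the long-term
  correlation stage needs.
- Demographics: age uniform 25–75, 60% male, weight 80 ± 15 kg, height
  170 ± 10 cm, no Black subjects by default (the race coefficient is
  still implemented and tested). Degenerate settings (equal bounds,
  zero SD) produce demographically homogeneous cohorts for
  sensitivity analyses.

Ground truth (class, GFR, production, Vd, noiseless starting values)
is kept in `truth_`-prefixed columns that the prediction pipeline
refuses to consume — recovery tests read them, predictors cannot.

**What the generator does not emulate**: changing plasma volume (and
hence Vd) from perioperative fluid shifts, non-renal clearance of
either marker, production drift (muscle wasting, corticosteroid
effects on cystatin C), assay batch effects, or any correlation
between demographics and outcome beyond what the base risk encodes.
Passing tests therefore demonstrate internal consistency of the
estimator and pipeline under the model's own assumptions — not
clinical performance on real cohorts, where these unmodelled effects
are the main sources of error.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to make Monte Carlo noise
small relative to the asserted margins: 1000 draws for the
steady-state identity, 1000 replicates × n = 60 for the DeLong null
size, n = 2000 cohorts for qualitative discrimination patterns, and
n = 400 homogeneous cohorts for production-method robustness. Large
cohort IDI checks use point estimates (no bootstrap); the pipeline
default is 500 resamples at study size, and the library default 2000.
Tolerances: steady-state identity 1e-9 relative; anuric limit 1e-6
absolute; IDI decomposition 1e-12; oracle grids 0.1 units. Ties in
ROC scores use midranks throughout; Youden ties break toward
sensitivity.

## Known limitations

- The production term inherits every bias of the steady-state equation
  used to back-calculate it; at high concentrations CKD-EPI
  back-calculation underestimates production relative to
  excretion-derived formulas. The sensitivity variants quantify but do
  not remove this.
- One-compartment kinetics mischaracterises the early distribution
  phase of both markers; the 4 h anchor partially hides this.
- The DeLong test and the logistic MLE are asymptotic; at n ≈ 50–60
  their finite-sample behaviour (mild size inflation, occasional
  separation) is visible and handled as described above.
- The generator's class structure makes discrimination considerably
  easier than in real cohorts (latent GFR distributions do not
  overlap), so absolute AUC/IDI magnitudes from the synthetic runs
  exceed what clinical data would give; only orderings and signs are
  meaningful.
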