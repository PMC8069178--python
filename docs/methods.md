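# Methods

This note documents the models, parameter choices and numerical decisions
behind `metsynkit`, and what the synthetic-data tests do and do not
demonstrate about real cohort data.

## One-pool tracer model and Steele estimators

The clamp simulator and the flux estimators share the single-pool
idealization: a well-mixed tracee pool of distribution volume V (L/kg)
receives endogenous appearance Ra(t) and a constant tracer infusion F, and
loses material through clearance-like disposal Rd = CL·C. Writing Qe and
Qt for tracee and tracer amounts per kg, both mass balances are linear with
rate constant k = CL/V:

    dQe/dt = Ra(t) − k·Qe        dQt/dt = F − k·Qt

Under insulin, Ra declines mono-exponentially from its basal value to the
suppressed plateau with a configurable half-time (default 30 min); the
paper-style protocol gives no dynamics, and the mono-exponential is the
simplest transient that genuinely exercises a non-steady-state estimator.
Because the system is linear the simulator evaluates the exact closed-form
solution — there is no integrator and no discretization error. Enrichment
is defined as the tracer mole fraction E = Qt/(Qe+Qt); with that
definition the steady state satisfies E = F/(Ra+F) and the dilution
estimator Ra = F/E − F is exact, which the tests verify to 1e-6 after long
equilibration.

The non-steady ("modified Steele") estimator applies, per consecutive
sample pair,

    Ra = (F̄ − p·V·C̄·ΔE/Δt)/Ē − F̄,    Rd = Ra − p·V·ΔC/Δt

with pairwise means C̄, Ē, F̄. Subtracting F̄ makes the steady limit
(ΔE = ΔC = 0) reduce exactly to F/E − F, i.e. to endogenous appearance
with the tracer contribution removed; the uncorrected F/E is available via
a flag. For glucose series the exogenous glucose infusion is additionally
subtracted so the reported Ra is endogenous production.

**Pool fraction and volume.** Defaults are p = 0.65 with V = 0.23 L/kg for
glycerol and 0.22 L/kg for glucose, the conventional single-pool values;
they are surfaced in `SteeleParams` because published protocols vary. A
perfectly mixed simulated pool corresponds to p = 1 with the true volume,
which is what the recovery tests pass; p < 1 only matters when the
concentration or enrichment is changing, and by the end of a four-hour
step the residual drift makes the choice numerically negligible (the
suppression-recovery error stays below ~0.5 percentage points either way).

**Suppression windows.** Basal Ra is a steady-state estimate over the
t ≤ 0 samples (the tracer has equilibrated for two hours; the simulated
pool turnover time is ~7 min, so the basal residual is below 1e-6).
Clamp Ra averages the non-steady estimates over the final 30 min of the
first insulin step. Negative flux estimates — possible with noisy
non-steady data — are flagged, never clipped, so data problems stay
visible.

## Synthetic cohort

The generator's defaults are the study conditions: 132 male subjects, 917
annotated metabolites, an IR fraction of 92/132, 14 planted 1-SD
insulin-resistance effects, 33 planted Framingham correlates (latent
correlation 0.4), one planted lipid–suppression association (0.6), a
lipolysis-suppression center of 68.1% with 8-point between-subject spread,
and 5% multiplicative clamp measurement noise.

Clinical covariates are drawn from independent log-normal/normal
distributions matched to the cohort's reported medians and IQRs (BMI
median ≈ 33.9 kg/m², insulin higher in the IR group, SBP ≈ 144 mmHg,
etc.); no attempt is made to reproduce the real covariance structure,
which is unpublished. Three couplings are planted deliberately: Rd is
drawn from group-conditional log-normals truncated at the 37.3
μmol·kg⁻¹·min⁻¹ cutoff so labels and classification agree by
construction; fasting insulin is group-conditional; and per-subject
suppression is anti-correlated with log HOMA-IR (Gaussian copula, ρ = 0.6)
so the clinical-correlate analysis has a true signal to find. Smoking
prevalence defaults to 25%; diabetes and antihypertensive treatment are
absent by default (a treatment-naive cohort), all configurable.

Metabolite abundances are log-normal with per-column location drawn over
roughly two orders of magnitude and log-SD in [0.3, 0.8]. The IR effect is
a mean shift of the configured size in SD units on the log scale;
Framingham and suppression effects share latent Gaussian structure with
the standardized log risk (computed through the package's own Framingham
scorer) and the true suppression vector. Missingness is purely
left-censored: cells whose latent value falls below the column's 25%
detection-limit quantile are censored with probability 0.6 (≈15% missing
cells overall). Superpathway labels are assigned in proportional blocks
such that the default panel contains exactly 451 Lipid metabolites, the
family used by the lipid-restricted suppression screen.

**What the generator does not emulate:** batch effects and run-day drift,
the unannotated metabolite fraction, inter-metabolite correlation beyond
the planted drivers, non-ignorable missingness other than left-censoring,
and any real biochemical structure in the annotations. Passing tests
therefore demonstrate that the estimators and screens recover known
effects under idealized sampling — not that the pipeline is robust to
measurement artifacts absent from the simulation.

## Preprocessing

Median rescaling divides each metabolite by the median of its non-missing
values (missing cells have no defined abundance, so they are excluded);
imputation then replaces each missing cell with half the smallest observed
value of that metabolite across all samples. The order — normalize first,
then impute — is fixed and pinned by a regression test; the two orders
genuinely differ because imputing first would shift the medians. After
rescaling every column's median equals 1 to 1e-12.

## Framingham risk

The lipid-based general-CVD Cox model is used (lipids are among the
inputs, so the BMI-based office variant does not apply). Coefficients ship
in a versioned JSON data file and are validated in the tests against the
source model's published worked example (10.48% for the reference
61-year-old female smoker) to 0.1 percentage point — hand-transcribed
coefficients without an oracle invite silent transcription error. Both
sexes are implemented although the default cohort is all-male. Cohort
records carry lipids in mmol/L and are converted internally
(38.67 mg/dL per mmol/L). The dichotomization convention is ≥ 12% = high.

## Screens and multiplicity

The Mann–Whitney U test uses the exact permutation null when n+m ≤ 20 and
the data are tie-free, and the tie-corrected normal approximation with
continuity correction otherwise; the exact path is checked against
exhaustive enumeration of all label assignments. Spearman correlations use
average ranks; over many metabolites the screen computes Pearson on ranks
with the t-approximation p-value, verified against the scalar routine.
A constant column yields an undefined correlation and is flagged (ρ = NaN,
p = 1) rather than raised, so family-wide screens keep running.

FDR control is Benjamini–Hochberg step-up (Benjamini–Yekutieli available
behind a flag), validated against a literal implementation of the step-up
definition. q-values are always computed within the family actually
screened — all annotated metabolites, the 451-member lipid family, or the
8-item clinical parameter list — because the family choice changes which
hits survive; the lipolysis section runs both metabolite families to make
that dependence visible. HOMA-IR is glucose[mmol/L] × insulin[μU/mL]/22.5
with 6.945 pmol/L per μU/mL.

## Nested cross-validation

Each iteration i seeds every stochastic element with base_seed + i: the
two iid standard-normal sanity columns, the stratified 80/20 split, the
inner 5-fold partition, and the learner. Hyperparameters are chosen by
inner-CV mean AUC (first-in-grid wins ties), the model is refit on the
full training split, and only the held-out 20% produces the recorded AUC —
a test asserts that scrambling the held-out rows cannot change the chosen
hyperparameters. Importances are XGBoost gain importances; aggregation is
the across-iteration mean, with selection frequency (fraction of
iterations in the per-iteration top-k, zero-importance features never
counting as selected) reported alongside. The across-iteration sd is the
reported uncertainty. Ranking ties break by descending frequency, then
lexicographic feature id, making top-k selection fully deterministic.

The default tuning grid is depth {2,3,4} × learning rate {0.05,0.1,0.3} ×
trees {50,100,200} × subsample {0.8,1.0}. Simulation studies and the test
suite use the reduced grid (depth {2,3}, rate 0.3, 30 trees, 32 histogram
bins), which keeps the full 10-cohort × 100-iteration recovery study
tractable on a single CPU while leaving the inner tuning step meaningful.

Because iterations resample one fixed cohort, per-iteration AUCs are
correlated: under the null the across-iteration mean has a
dataset-conditional spread of a few hundredths around 0.5 (spurious
feature–label correlations in train and test splits are anti-correlated),
which is why the null-calibration band is [0.40, 0.60] rather than a
binomial interval.

## Problem sizes used in the checks

The recovery study runs 10 replicate default cohorts through the
100-iteration protocol with the reduced grid; null-screen calibration uses
500 cohorts of 132 × 200; nested-CV null calibration uses 20 iterations on
132 × 200; the end-to-end determinism check runs the full study twice at
10 iterations. The acceptance script mirrors these at slightly smaller
replicate counts (200 null screens, one 40-iteration study) and reports
the sizes alongside each value.

## Known limitations

- The one-pool model with clearance-like disposal is an idealization;
  multi-compartment kinetics, deuterium recycling and priming-dose
  effects are out of scope.
- The insulin dose of the protocol's second clamp step is not modeled;
  suppression uses the first step only, and step2 data pass through
  untouched.
- Clinical covariates are independent apart from the planted couplings,
  so multivariate structure among covariates is not represented.
- The Framingham engine implements only the 2008 lipid-based general-CVD
  model; other risk engines are out of scope.
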