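# metsynkit

Analysis toolkit for metabolic-syndrome cohort studies that combine
hyperinsulinemic euglycemic clamp tracer kinetics, untargeted plasma
metabolomics and cardiovascular risk scoring. It is aimed at researchers
who want a tested, reproducible implementation of the full analysis chain —
from raw clamp time courses and metabolite abundance matrices to
FDR-controlled screens and cross-validated classification models — together
with a synthetic-cohort generator so every stage can be exercised against
known ground truth.

## What it computes

**Tracer fluxes (Steele single-pool equations).** From a primed-continuous
tracer infusion *F* (μmol·kg⁻¹·min⁻¹), plasma tracee concentration *C*
(μmol/L) and tracer enrichment *E*, the rate of appearance is

- steady state: Ra = F/E − F
- non-steady state: Ra = (F̄ − p·V·C̄·ΔE/Δt)/Ē − F̄, with pool fraction
  *p* and distribution volume *V* (L/kg), and Rd = Ra − p·V·ΔC/Δt.

Percent insulin suppression of glycerol Ra
(Ra-supp = 100·(Ra_basal − Ra_clamp)/Ra_basal) indexes adipose-tissue
insulin sensitivity; peripheral insulin resistance is classified from the
glucose disposal rate (IR iff Rd < 37.3 μmol·kg⁻¹·min⁻¹).

**Framingham 10-year general-CVD risk** — the sex-specific Cox model on
ln(age), ln(total cholesterol), ln(HDL), ln(SBP) (treated/untreated),
smoking and diabetes: risk% = 100·(1 − S0^exp(LP − mean LP)), with a
dichotomization at 12% (≥ 12% is "high").

**Metabolite preprocessing** — per-metabolite median rescaling to 1, then
half-minimum imputation of below-detection-limit cells.

**Univariate screens** — Mann–Whitney U group contrasts and Spearman rank
correlations over all metabolites, Benjamini–Hochberg q-values computed
within the screened family (all annotated metabolites, the lipid
superpathway, or a clinical parameter list), plus HOMA-IR.

**Nested cross-validated classification** — 100 structured iterations of:
add two random "sanity" columns, stratified 80/20 split, inner 5-fold
grid search for XGBoost hyperparameters, refit, record test AUC and gain
importances. Mean ± sd AUC is the model result; the top-20 aggregated
features are re-modelled with the identical protocol.

**Synthetic cohorts** — clinical tables, log-normal metabolite matrices
with planted group shifts / correlations and left-censored missingness, and
analytically forward-simulated one-pool clamp tracer curves, all
deterministic given a seed.

## Worked example

```python
import metsynkit as mk
from metsynkit.harness import CVConfig, REDUCED_GRID

cfg = mk.StudyConfig(cv=CVConfig(n_iterations=30, param_grid=dict(REDUCED_GRID)))
report = mk.run_study(cfg, seed=7, out_dir="study_out")

print(len(mk.significant(report.ir_screen)))        # 13
print(len(mk.significant(report.fram_correlates)))  # 31
print(round(report.ml_all.mean_auc, 2))             # 0.73
print(round(report.ml_top20.mean_auc, 2))           # 0.88
print(round(report.lipolysis.suppressions.median(), 1))  # 69.3
```

On this seed the default cohort (132 men, 917 metabolites, 14 planted
insulin-resistance effects and 33 planted CVD-risk correlates) yields 13
metabolites separating IR from non-IR men at q < 0.05, 31 metabolites
correlated with the Framingham score, a modest all-features classification
AUC (0.73) that improves to 0.88 when the model is restricted to its own
top-20 features, and a median glycerol-Ra suppression of 69.3% in the
39-subject clamp subset (the generator plants a cohort center of 68.1%).
`study_out/` then holds the screen tables, flux and suppression CSVs,
Framingham scores and a `summary.json`; rerunning with the same seed
reproduces every file byte for byte.

The same stages are scriptable from the shell:

```bash
metsynkit simulate --out cohort/ --seed 1
metsynkit preprocess --abundances cohort/metabolites.tsv \
    --annotations cohort/annotations.tsv --out cohort/pre.tsv
metsynkit flux --in cohort/clamp.csv --out cohort/flux.csv
metsynkit run-study --out study/ --seed 1
```

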