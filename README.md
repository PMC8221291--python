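# telomethyl

Explanatory modelling of newborn telomere length and early-life telomere
attrition from cord-blood DNA methylation.

Telomere length at birth varies widely between newborns and predicts
later-life telomere reserve, but its molecular correlates at birth are
poorly understood. `telomethyl` implements an end-to-end pipeline that
models a telomere outcome `Y` (cord-blood T/S ratio, or the
regression-to-the-mean–corrected attrition rate between birth and a
childhood follow-up) as a sparse weighted sum of CpG methylation levels
and their pairwise interactions:

    Y_i = w_0 + Σ_k w_k X_ik + Σ_{s,t} v_st X_is X_it

with CpGs standardized before entering the model. Because hundreds of
thousands of correlated CpGs compete to explain one outcome in a few
hundred samples, selection proceeds in guarded stages:

1. **EWAS pre-screen** — one robust (HC3) linear model per CpG, adjusted
   for perinatal covariates and cell-type fractions; test statistics
   recalibrated against their empirical null (bias and inflation by
   median/MAD); candidates at corrected p < 0.01.
2. **Adaptive lasso** on all candidates jointly, with penalty weights
   `1/|ridge coefficient|`, λ by 10-fold CV with the one-SE rule.
3. **Stability elastic net** over the candidates plus all their pairwise
   interaction products: 1000 draws of 85% of samples, the mixing α tuned
   per draw over 0–1 (step 0.05); terms selected in ≥95% of draws are kept.
4. **Term expansion and ridge finalization** — member CpGs of selected
   interactions join the main effects; final weights come from a ridge fit
   on the whole data with bootstrap p-values per coefficient.

Attrition is computed with regression-to-the-mean correction
(`dTL = ρθ(X1−μ1) − (X2−μ2)`), and selected CpGs are interpreted through
CpG–transcript correlation (shared gene or ±1 Mb) and hypergeometric
pathway over-representation on GMT gene sets.

Since cohort methylation data are access-restricted, the package ships a
first-class synthetic cohort generator that emulates the full data
structure — correlated CpG blocks, covariates, planted sparse truth with
interactions, two-timepoint telomere measurements with qPCR-like error,
expression, annotation and gene sets — so every stage is testable against
a known ground truth. See `docs/methods.md` for the statistical detail.

## Worked example

```python
from telomethyl import (SimConfig, MethylomeTelomereModel,
                        PenalizedFitConfig, rtm_corrected_attrition)
from telomethyl.simulate import generate_cohort
from telomethyl.qc import run_qc

cohort = generate_cohort(SimConfig(n_samples=150, n_cpgs=400, n_blocks=50,
                                   n_true_main=5, n_true_inter=1, seed=7))
beta, qc_report = run_qc(cohort.beta, cohort.annotation)

attr = rtm_corrected_attrition(cohort.telomeres)
print(attr.rho_hat, attr.theta_hat)   # 0.841 1.059

model = MethylomeTelomereModel.from_cohort(
    cohort, config=PenalizedFitConfig(b_stability=25, b_bootstrap=50, seed=3))
model.beta = beta
res = model.fit()
print(res.summary())
```

```
Methylome telomere model
================================================================
samples: 150    CpGs screened: 381
EWAS candidates (corrected p < 0.01): 12
adaptive-lasso mains: 6    stability subsamples: 25
final terms: 7 (6 mains + 1 interactions)
Pearson r = 0.820    R^2 = 0.672    ridge lambda = 2.479
----------------------------------------------------------------
                 term  weight        kind  p_bootstrap
           cg00000049 +0.0295        main         0.02
           cg00000144 -0.0235        main         0.02
           cg00000309 +0.0255        main         0.02
           cg00000316 +0.0347        main         0.02
           cg00000354 +0.0193        main         0.04
           cg00000398 +0.0173        main         0.02
cg00000144:cg00000354 +0.0174 interaction         0.02
```

The fitted weighted sum correlates r = 0.82 with the simulated baseline
telomere length (R² = 0.67). All five planted main-effect CpGs and the
planted interaction (`cg00000144:cg00000354`) are recovered;
`cg00000398` is a stable false positive of the kind the methods note
discusses (a screen survivor with genuine in-sample correlation). The
ρ̂ = 0.84 and θ̂ = 1.06 are the plug-in moments of the attrition
correction. Bootstrap p-values are floored at 1/B (here B = 50 in the
demo profile).

A shell interface mirrors the library (`telomethyl simulate`,
`telomethyl run-all`, `telomethyl attrition`, `telomethyl qc`,
`telomethyl simulate-run`); `run-all` writes per-stage TSV tables and a
JSON manifest that makes reruns byte-identical.

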