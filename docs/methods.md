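# Methods

`telomethyl` builds explanatory models of two telomere outcomes in a birth
cohort — telomere length at birth (cord blood T/S ratio) and the early-life
telomere attrition rate — as sparse weighted sums of cord-blood DNA
methylation levels and their pairwise interactions. This note records the
statistical procedures, the tunable parameters, the synthetic cohort the
package tests itself against, and the numerical and design choices that were
genuinely open.

## Outcomes

**Baseline telomere length** is the measured cord-blood T/S ratio.

**Attrition** is corrected for regression to the mean. With `X1` baseline
and `X2` follow-up T/S ratios,

    dTL_i = rho * theta * (X1_i - mu1) - (X2_i - mu2),

where `rho` is the Pearson correlation between timepoints, `theta` the
ratio of follow-up to baseline standard deviations (n−1 denominators
throughout), and `mu1`, `mu2` the sample means. Positive `dTL` means the
follow-up fell below its regression-adjusted expectation, i.e. attrition.
The attrition rate divides by each child's follow-up age (T/S per year).
With plug-in sample moments the corrected attrition has mean exactly zero —
an invariant the tests assert on every input. Only its dispersion and
per-child ordering are informative; a non-zero mean can only arise from
computing the moments on a different subset than the corrected values.

Two descriptive tests accompany the panel: a paired t-test on the raw
difference, and a Pitman–Morgan test of variance homogeneity for paired
measurements (t-transform of the correlation between sums and differences,
n−2 df). The variance test assumes joint normality and is exposed behind a
`method=` strategy argument so an alternative correlated-variance statistic
can be swapped in.

## Methylation QC

Beta values are `M/(M+U)` from methylated/unmethylated intensities, in
[0, 1]. The QC chain, in order: call-rate filtering (a cell is detected iff
its detection p ≤ 1e-16; probes detected in <95% of samples are dropped,
then samples detected in <98% of remaining probes), K-nearest-neighbour
imputation, per-CpG outlier trimming at 3 IQR beyond the quartiles
(linear-interpolation quantiles — trimming outcomes depend on the quantile
rule, so it is fixed and stated), and probe exclusion (X/Y chromosomes,
SNP-overlapping, cross-reactive). Trimming after imputation re-introduces
holes; those cells are re-completed by CpG means (logged) so downstream
stages always see a dense matrix. KNN imputation (default k = 10) measures
distances between CpG columns on a mean-completed copy and fills each hole
with the mean of the k nearest CpGs observed for that sample; the p × p
distance matrix makes it quadratic in panel size, fine at the scales this
pipeline targets. Normalization, batch correction and cell-type
deconvolution are upstream concerns: the pipeline consumes their outputs
(cell fractions arrive as covariates).

## EWAS pre-screening

One OLS per CpG relates the outcome to that CpG (original beta scale, no
standardization) plus a fixed a-priori covariate set: newborn sex,
ethnicity, birth weight, gestational age; maternal age, pre-pregnancy BMI,
parity, education, smoking, pregnancy complications; paternal age; and six
of the seven cord-blood cell fractions (one dropped — they sum to one).
Standard errors are HC3 sandwich estimates; z = beta/se with normal
reference.

The z statistics are then recalibrated against their **empirical null**:
bias = median(z), inflation = normal-consistent MAD(z). Corrected
statistics are (z − bias)/inflation with two-sided normal p-values. The
median/MAD summary of the central mass is deterministic, desk-scale, and
insensitive to a few percent of true signal in the tails (asserted by
simulation); a model-based mixture estimator could be substituted behind
the same bias-plus-inflation contract. Benjamini–Hochberg q-values flag
individually significant probes at FDR 5%; the *screening* rule for the
selection stage is the looser corrected p < 0.01, chosen to admit CpGs that
act jointly without being individually significant.

## Selection

All penalized fits minimize the glmnet-parameterized objective
`(1/2N)·RSS + lam·[(1−alpha)/2·||w||² + alpha·||w||₁]` on standardized CpGs
(mean 0, sd 1, n−1 denominator). Lambda paths are log-spaced from
`lam_max = max|X'y|/(N·max(alpha, 1e-3))` down to a floor of 0.02·lam_max
(25 values): the one-SE rule always resolves well above the prediction-
oriented deep tail, so the path stops early by design. `lambda_1se` is the
largest lambda whose mean 10-fold-CV deviance is within one standard error
of the minimum.

1. **Adaptive lasso** on all screened candidates jointly. Penalty weights
   are inverse absolute ridge coefficients (ridge lambda by CV at minimum
   deviance); ridge magnitudes below 1e-8 are floored before inversion,
   capping the penalty rather than producing infinities. The weighted
   problem is solved by the standard column-rescaling reduction to a plain
   lasso at its `lambda_1se` (the equivalence is asserted against an
   independent solver route).
2. **Interactions**: all pairwise products of the standardized selected
   CpGs, not re-standardized (their variance therefore differs from 1),
   canonically ordered by id pair.
3. **Stability elastic net**: B subsamples (default 1000; the demo profile
   uses 200) of 85% of samples, drawn without replacement, subsample b
   seeded as seed+b so parallel and serial execution agree. Within each
   subsample the mixing parameter alpha is tuned over 0..1 in steps of
   0.05 — one shared fold assignment across the grid, CV deviance compared
   at each alpha's `lambda_1se`, ties broken toward larger alpha (sparser)
   — and the model refit at the winning pair. A term is selected iff its
   coefficient is nonzero there. Terms selected in ≥95% of subsamples are
   active. Per-subsample (alpha, lambda_1se, n_selected) records are kept
   for the variability report.
4. **Term expansion**: member CpGs of active interactions that are not
   active mains join the main-effect set (interactions unchanged).
5. **Final ridge fit** on the whole data (lambda by CV minimum), reporting
   the Pearson r between outcome and fitted weighted sum and R² = r².
   Coefficient p-values come from nonparametric case-resampling bootstrap
   (default 10,000 replicates; demo 1,000) refitting the ridge at the
   fixed full-data lambda; two-sided p = 2·min(P(w*≤0), P(w*≥0)), floored
   at 1/B. Re-tuning lambda inside every replicate is supported in
   principle but off: it multiplies cost by the CV factor without changing
   the inferential target.

The outcome enters selection unadjusted (matching the weighted-sum model
form; covariates act in the screen only); `residualize=True` pre-regresses
the outcome on the covariates first.

Ridge solutions — weight construction, final fit, and every bootstrap
replicate — use the closed-form SVD solution rather than coordinate
descent: exact, and cheap enough for thousands of refits. Coordinate
descent (scikit-learn) handles every l1-containing fit; its tolerance is
the solver's relative duality gap, 1e-4 for fits and 3e-3 for CV-grid
deviance evaluation only (verified to leave selected sets unchanged —
held-out deviances are means over samples and insensitive to the last
digits of the training fit).

## Enrichment

Selected CpGs pair with transcripts by shared gene symbol
(case-insensitive, any location) or by cis proximity (same chromosome,
transcript start within 1 Mb of the CpG, closed interval; coordinates are
1-based). Pair counts and distinct-transcript counts are both reported —
one transcript can correlate with several CpGs, so the two counts
legitimately differ. Pearson correlations on shared complete samples
survive at p < 0.05; the survivors' gene symbols form the ORA query.
Pathway over-representation is the hypergeometric upper tail of the
query/pathway overlap in a configurable gene universe (default: all genes
annotated on the expression fixture), with BH control; a pathway is
significant iff q < 0.05 AND at least 3 query genes overlap — both
conditions, boundaries excluded.

## Synthetic cohort

The generator emulates the cohort structure the analysis assumes, with
defaults set to the emulated cohort's characteristics: n = 247 newborns,
follow-up age 4.58 (SD 0.39) years, baseline T/S 1.17 (SD 0.27), attrition
rate SD 0.030 T/S per year.

- **Methylation**: a latent Gaussian per CpG, equicorrelated in blocks of
  ~8 CpGs at correlation 0.4 (local island/shore-like covariation; random
  genome-wide probe pairs correlate only weakly), squashed to (0,1) by a
  logistic transform with per-CpG location and scale. Missingness is
  injected completely at random (default 1%).
- **Planted truth**: disjoint sparse models for the two outcomes — default
  10 main-effect CpGs and 2 interactions each, with relative weights drawn
  from (0.8, 1.2) and random signs. Only weight *ratios* matter: the noise
  is scaled afterwards so the planted terms explain the target share
  (default R² = 0.7) of the latent outcome variance. Near-equal weights
  are deliberate — splitting R² = 0.7 over 12 terms caps each marginal
  correlation near 0.24, and wide weight dispersion would push the weakest
  effects below any screen's detection floor. The first interaction pairs
  two main-effect CpGs (recoverable by a screen-then-interact pipeline);
  later ones include a CpG absent from the main set, exercising the
  term-expansion rule. The covariate contribution (gestational age and
  sex) is fixed at 5% of outcome variance; covariate and noise parts are
  orthogonalized against the signal and scaled to exact in-sample shares,
  so the planted R² is reproducible to overfitting order p/n rather than
  Monte-Carlo order.
- **Telomeres**: follow-up true TL = baseline − age × planted rate. Both
  timepoints then receive independent multiplicative log-normal
  measurement noise with CV 0.06 — the noise share implied by the qPCR
  assay's inter-assay reliability (ICC ≈ 0.94 leaves ≈6% of T/S variance
  to measurement). This dilutes the *observed* planted R² to roughly
  0.93 × target for baseline, and substantially more for the attrition
  rate (noise at both timepoints propagates through the correction), as
  in real data.
- **Cell fractions** come from a Dirichlet centred on cord-blood norms
  (granulocyte-dominated); they enter the covariate adjustment but not the
  planted model, probing confounder handling.
- **Expression/annotation/gene sets**: a configurable fraction of
  transcripts is coupled to CpGs (shared gene or within 1 Mb) at a set
  correlation; annotation assigns chromosomes, 1-based positions, gene
  symbols (some CpGs unannotated), promoter/DMR flags, and configurable
  SNP/cross-reactive fractions for filter testing; planted-truth CpGs are
  kept autosomal and unflagged so QC cannot remove them. One gene set
  collects the true baseline CpGs' genes as an enrichment positive
  control.

**What passing tests do and do not show.** The generator reproduces the
statistical *structure* the method assumes — sparse planted signal,
correlated blocks, two-timepoint measurement error — but not array
chemistry, batch structure, cell-composition confounding of CpGs, or
genetic effects on telomere length. Recovery results on synthetic cohorts
therefore validate the machinery, not the biology of any real cohort.

## Desk-scale recovery: what the simulation study shows

The recovery study (n = 250, p = 2000 CpGs, 10 true mains + 2
interactions, target R² = 0.7, 200 stability subsamples, metrics averaged
over seeded replicates — sizes chosen so the whole study runs in minutes
on one CPU) exposes two structural properties of screen-then-select
pipelines that users should expect on real data too:

- **Screen power bounds sensitivity.** With R² = 0.7 split over 12 terms,
  each true CpG's marginal correlation is ≈0.23 (z ≈ 3.6 at n = 250), so
  the corrected-p < 0.01 screen (|z| > 2.58) passes each true main with
  probability ≈0.85–0.9, not ≈1. Sensitivity of the full pipeline tracks
  this screen power.
- **Screening and selecting on the same sample couples their errors.**
  Null CpGs that pass the screen do so *because* they correlate with the
  outcome in this sample (|r| ≳ 0.16); that correlation is a property of
  the whole sample, so cross-validation and 85% subsampling both see it,
  and such CpGs are stably selected at frequencies near 1. The
  false-discovery proportion of the selected set against the planted truth
  is therefore substantially above what the stability threshold alone
  would suggest — at these scaled-down conditions we observe FDP ≈ 0.4–0.5
  with ≈3–6 such stable false mains per run. An independent replication
  sample, not a different threshold, is what would remove this effect.

## Known limitations

- The empirical-null estimator is a robust location/scale summary, not a
  mixture model; heavy polygenic signal (a large non-null fraction) would
  bias it.
- The Pitman–Morgan variance test is exact only under joint normality;
  skewed T/S distributions inflate its size (demonstrated in tests).
- KNN imputation averages neighbour values directly, which is biased when
  neighbouring CpGs sit at different mean levels; it wins over CpG-mean
  imputation on level-homogeneous correlated data.
- Bootstrap p-values keep the ridge lambda fixed at the full-data choice;
  they quantify coefficient stability at that penalty, not selection
  uncertainty.
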