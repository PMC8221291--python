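"""Synthetic birth-cohort generator.

Emulates the data structure the analysis assumes: a cord-blood methylation
beta matrix with LD-like correlated CpG blocks, a perinatal covariate table
(including cord-blood cell-type fractions), paired two-timepoint telomere
measurements with qPCR-like multiplicative error, and matching annotation,
expression and gene-set fixtures.

The planted generative model mirrors the analysis target: baseline telomere
length is an intercept plus a sparse weighted sum of standardized CpGs and
pairwise CpG products, a small covariate contribution, and Gaussian noise
scaled so the planted signal explains a requested fraction of variance.
A disjoint CpG set drives the attrition-rate process; follow-up telomere
length is baseline minus age times that rate. Both timepoints then receive
independent multiplicative log-normal measurement noise (a ratio-scale qPCR
quantity), and beta values lose entries completely at random.

Defaults follow the characteristics of the cohort being emulated: 247 newborns, mean
follow-up age 4.58 (SD 0.39) years, baseline T/S 1.17 (SD 0.27), attrition
rate SD 0.030 T/S per year, and measurement noise consistent with qPCR
inter-assay reliability (ICC ~0.94 implies a noise share of ~6% of the T/S
variance, i.e. CV ~0.06 at mean T/S 1.17).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .qc import BetaMatrix
from .telomere import TelomerePanel
from .selection import interaction_id

__all__ = [
    "SimConfig",
    "TrueModel",
    "PlantedOutcome",
    "ExpressionSet",
    "SyntheticCohort",
    "generate_cohort",
    "generate_annotation",
    "generate_expression",
    "generate_genesets",
    "write_cohort",
]

CELL_TYPES = ["nrbc", "gran", "mono", "nk", "bcell", "cd4t", "cd8t"]
# Dirichlet means near cord-blood norms (granulocyte-dominated)
CELL_MEANS = np.array([0.05, 0.55, 0.08, 0.05, 0.08, 0.13, 0.06])
AUTOSOMES = [str(c) for c in range(1, 23)]


@dataclass
class SimConfig:
    """Study-condition parameters for a synthetic cohort."""

    n_samples: int = 247
    n_cpgs: int = 2000
    # short LD-like blocks (~8 CpGs) at moderate correlation: genome-wide
    # probes correlate locally (islands/shores) but only weakly at random
    n_blocks: int = 250
    within_block_corr: float = 0.4
    n_true_main: int = 10
    n_true_inter: int = 2
    # relative weights: only ratios matter, noise is scaled to target_r2
    effect_size_range: tuple[float, float] = (0.8, 1.2)
    target_r2: float = 0.7
    covariate_r2: float = 0.05
    measurement_cv: float = 0.06
    missing_rate: float = 0.01
    seed: int = 0
    # T/S and age scales of the emulated cohort
    tl_mean: float = 1.17
    tl_sd: float = 0.27
    rate_mean: float = 0.0007
    rate_sd: float = 0.030
    age_mean: float = 4.58
    age_sd: float = 0.39

    def __post_init__(self) -> None:
        if self.n_true_main + 2 * self.n_true_inter > self.n_cpgs:
            raise ValueError("planted model larger than the CpG panel")
        if not 0 <= self.target_r2 < 1:
            raise ValueError("target_r2 must lie in [0, 1)")
        if self.target_r2 + self.covariate_r2 >= 1:
            raise ValueError("required effect variance exceeds total variance")
        if not 0 <= self.within_block_corr < 1:
            raise ValueError("within_block_corr must lie in [0, 1)")
        if self.measurement_cv < 0:
            raise ValueError("measurement_cv must be non-negative")


@dataclass
class PlantedOutcome:
    """Planted sparse truth for one outcome."""

    main_ids: list[str]
    main_weights: np.ndarray
    interactions: list[tuple[str, str]]
    interaction_weights: np.ndarray

    @property
    def interaction_ids(self) -> list[str]:
        return [interaction_id(s, t) for s, t in self.interactions]

    @property
    def member_ids(self) -> list[str]:
        out = list(self.main_ids)
        for s, t in self.interactions:
            for m in (s, t):
                if m not in out:
                    out.append(m)
        return out

    @property
    def term_ids(self) -> list[str]:
        return self.main_ids + self.interaction_ids


@dataclass
class TrueModel:
    baseline: PlantedOutcome
    attrition: PlantedOutcome
    noise_baseline: np.ndarray       # multiplicative measurement noise, timepoint 1
    noise_followup: np.ndarray       # multiplicative measurement noise, timepoint 2
    tl_baseline_true: np.ndarray     # noise-free T/S at baseline
    rate_true: np.ndarray            # noise-free attrition rate


@dataclass
class ExpressionSet:
    values: pd.DataFrame             # samples x transcripts
    annotation: pd.DataFrame         # indexed by transcript id: gene, chrom, start
    linked_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class SyntheticCohort:
    beta: BetaMatrix
    covariates: pd.DataFrame
    telomeres: TelomerePanel
    truth: TrueModel
    annotation: pd.DataFrame
    expression: ExpressionSet
    genesets: dict[str, list[str]]
    config: SimConfig | None = None


def _planted_outcome(rng: np.random.Generator, cpg_ids: list[str],
                     available: list[int], config: SimConfig) -> PlantedOutcome:
    """Draw a sparse truth: mains, then interactions partly outside the mains.

    The first interaction pairs two main-effect CpGs (recoverable by the
    screen-then-interact pipeline); later ones pair a main with a fresh CpG,
    exercising the term-expansion rule downstream.
    """
    lo, hi = config.effect_size_range
    k, q = config.n_true_main, config.n_true_inter
    mains = list(rng.choice(available, size=k, replace=False))
    pool = [i for i in available if i not in set(mains)]
    inters: list[tuple[int, int]] = []
    for j in range(q):
        if j == 0 and k >= 2:
            pair = tuple(rng.choice(mains, size=2, replace=False))
        else:
            extra = int(rng.choice(pool))
            pool.remove(extra)
            pair = (int(rng.choice(mains)), extra)
        inters.append(pair)
    w = rng.uniform(lo, hi, size=k) * rng.choice([-1.0, 1.0], size=k)
    v = rng.uniform(lo, hi, size=q) * rng.choice([-1.0, 1.0], size=q)
    return PlantedOutcome(
        main_ids=[cpg_ids[i] for i in mains], main_weights=w,
        interactions=[(cpg_ids[s], cpg_ids[t]) for s, t in inters],
        interaction_weights=v)


def _outcome_signal(Xstd: pd.DataFrame, truth: PlantedOutcome) -> np.ndarray:
    s = Xstd[truth.main_ids].to_numpy() @ truth.main_weights
    for (a, b), v in zip(truth.interactions, truth.interaction_weights):
        s = s + v * Xstd[a].to_numpy() * Xstd[b].to_numpy()
    return s


def _orthogonal_part(v: np.ndarray, others: list[np.ndarray]) -> np.ndarray:
    """Residual of v after projecting out an intercept and ``others``."""
    X = np.column_stack([np.ones(len(v))] + others) if others \
        else np.ones((len(v), 1))
    return v - X @ np.linalg.lstsq(X, v, rcond=None)[0]


def _scale_outcome(rng: np.random.Generator, signal: np.ndarray,
                   covariate_part: np.ndarray, config: SimConfig,
                   ) -> np.ndarray:
    """Mix signal, covariates and noise to the requested variance shares.

    The covariate and noise parts are orthogonalized against the planted
    signal and rescaled to their exact in-sample variance shares, so that
    regressing the latent outcome on the true terms recovers target_r2 up
    to overfitting of order p/n rather than Monte-Carlo variance.
    """
    n = signal.shape[0]
    var_s = signal.var(ddof=1)
    if config.target_r2 > 0 and var_s == 0:
        raise ValueError("planted signal has zero variance")
    var_total = var_s / config.target_r2 if config.target_r2 > 0 else 1.0
    var_c = config.covariate_r2 * var_total
    var_e = var_total - var_s - var_c
    if var_e < 0:
        raise ValueError("required effect variance exceeds total variance")
    c = _orthogonal_part(covariate_part, [signal] if var_s > 0 else [])
    c = c / max(c.std(ddof=1), 1e-12) * np.sqrt(var_c)
    e = _orthogonal_part(rng.standard_normal(n),
                         [signal, c] if var_s > 0 else [c])
    e = e / max(e.std(ddof=1), 1e-12) * np.sqrt(var_e)
    return signal + c + e


def _covariate_table(rng: np.random.Generator, config: SimConfig) -> pd.DataFrame:
    n = config.n_samples
    sex = rng.integers(0, 2, n)
    ga = rng.normal(39.24, 1.37, n)
    bw = rng.normal(3400, 430, n) + 110 * (ga - 39.24)
    m_age = rng.normal(29.5, 4.2, n)
    cells = rng.dirichlet(CELL_MEANS * 60, size=n)
    df = pd.DataFrame({
        "sex": sex,
        "ethnicity_european": rng.binomial(1, 0.935, n),
        "birth_weight": bw,
        "gestational_age": ga,
        "maternal_age": m_age,
        "maternal_bmi": np.exp(rng.normal(np.log(24.0), 0.16, n)),
        "parity": rng.choice([1, 2, 3], size=n, p=[0.55, 0.33, 0.12]),
        "maternal_education": rng.choice([0, 1, 2], size=n, p=[0.2, 0.4, 0.4]),
        "maternal_smoking": rng.binomial(1, 0.12, n),
        "pregnancy_complications": rng.binomial(1, 0.15, n),
        "paternal_age": m_age + rng.normal(2.2, 3.5, n),
    })
    for i, ct in enumerate(CELL_TYPES):
        df[f"cell_{ct}"] = cells[:, i]
    df["age_followup"] = np.clip(rng.normal(config.age_mean, config.age_sd, n), 3.0, None)
    df.index = [f"S{i:04d}" for i in range(n)]
    return df


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; bit-reproducible given the seed."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_cpgs
    cpg_ids = [f"cg{j:08d}" for j in range(p)]
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # equicorrelated blocks via a shared Gaussian factor, squashed to (0,1)
    block_of = np.arange(p) % config.n_blocks
    g = rng.standard_normal((n, config.n_blocks))
    eps = rng.standard_normal((n, p))
    r = config.within_block_corr
    z = np.sqrt(r) * g[:, block_of] + np.sqrt(1.0 - r) * eps
    mu = rng.uniform(-2.5, 2.5, p)
    sc = rng.uniform(0.3, 0.8, p)
    beta_clean = expit(mu[None, :] + sc[None, :] * z)
    beta_df = pd.DataFrame(beta_clean, index=sample_ids, columns=cpg_ids)

    covariates = _covariate_table(rng, config)

    # disjoint planted truths for the two outcomes
    available = list(range(p))
    truth_base = _planted_outcome(rng, cpg_ids, available, config)
    used = {cpg_ids.index(c) for c in truth_base.member_ids}
    truth_attr = _planted_outcome(rng, cpg_ids, [i for i in available if i not in used],
                                  config)

    sds = beta_df.std(axis=0, ddof=1)
    Xstd = (beta_df - beta_df.mean(axis=0)) / sds
    zero = config.target_r2 == 0
    if zero:
        truth_base.main_weights = np.zeros_like(truth_base.main_weights)
        truth_base.interaction_weights = np.zeros_like(truth_base.interaction_weights)
        truth_attr.main_weights = np.zeros_like(truth_attr.main_weights)
        truth_attr.interaction_weights = np.zeros_like(truth_attr.interaction_weights)

    cov_part = (0.6 * (covariates["gestational_age"] - 39.24) / 1.37
                + 0.4 * (covariates["sex"] - 0.5)).to_numpy()

    y_base = _scale_outcome(rng, _outcome_signal(Xstd, truth_base), cov_part, config)
    tl1 = config.tl_mean + config.tl_sd * (y_base - y_base.mean()) / max(y_base.std(ddof=1), 1e-12)
    tl1 = np.clip(tl1, 0.05, None)

    y_attr = _scale_outcome(rng, _outcome_signal(Xstd, truth_attr), cov_part, config)
    rate = config.rate_mean + config.rate_sd * (y_attr - y_attr.mean()) / max(y_attr.std(ddof=1), 1e-12)
    age = covariates["age_followup"].to_numpy()
    tl2 = np.clip(tl1 - age * rate, 0.05, None)

    sigma = np.sqrt(np.log1p(config.measurement_cv ** 2))
    noise1 = np.exp(rng.normal(-sigma ** 2 / 2, sigma, n))
    noise2 = np.exp(rng.normal(-sigma ** 2 / 2, sigma, n))
    panel = TelomerePanel(x1=tl1 * noise1, x2=tl2 * noise2, age=age,
                          sample_ids=sample_ids)

    beta_obs = beta_clean.copy()
    if config.missing_rate > 0:
        mask = rng.random((n, p)) < config.missing_rate
        beta_obs[mask] = np.nan
    beta = BetaMatrix(beta_obs, sample_ids, cpg_ids)

    truth = TrueModel(baseline=truth_base, attrition=truth_attr,
                      noise_baseline=noise1, noise_followup=noise2,
                      tl_baseline_true=tl1, rate_true=rate)

    protected = set(truth_base.member_ids) | set(truth_attr.member_ids)
    annotation = generate_annotation(p, seed=config.seed + 1, cpg_ids=cpg_ids,
                                     protected=protected)
    cohort = SyntheticCohort(beta=beta, covariates=covariates, telomeres=panel,
                             truth=truth, annotation=annotation,
                             expression=ExpressionSet(pd.DataFrame(index=sample_ids),
                                                      pd.DataFrame()),
                             genesets={}, config=config)
    cohort.expression = generate_expression(cohort, n_transcripts=max(200, p // 10),
                                            linked_fraction=0.3,
                                            seed=config.seed + 2)
    cohort.genesets = generate_genesets(cohort, n_sets=30, seed=config.seed + 3)
    return cohort


def generate_annotation(n_cpgs: int, seed: int, cpg_ids: list[str] | None = None,
                        xy_fraction: float = 0.03, snp_fraction: float = 0.02,
                        cross_reactive_fraction: float = 0.02,
                        unannotated_fraction: float = 0.15,
                        protected: set[str] | None = None) -> pd.DataFrame:
    """Probe annotation: chromosome, 1-based position, gene, region flags.

    A configurable fraction of probes lands on X/Y or carries SNP /
    cross-reactivity flags (for filter testing); ``protected`` ids are kept
    autosomal and unflagged so planted-truth CpGs survive QC. Some CpGs have
    no gene annotation, as on real arrays.
    """
    if n_cpgs <= 0:
        raise ValueError("n_cpgs must be positive")
    rng = np.random.default_rng(seed)
    if cpg_ids is None:
        cpg_ids = [f"cg{j:08d}" for j in range(n_cpgs)]
    protected = protected or set()
    prot = np.array([c in protected for c in cpg_ids])
    chrom = rng.choice(AUTOSOMES, size=n_cpgs)
    on_xy = (rng.random(n_cpgs) < xy_fraction) & ~prot
    chrom[on_xy] = rng.choice(["X", "Y"], size=int(on_xy.sum()))
    pos = rng.integers(1, 150_000_000, size=n_cpgs)
    n_genes = max(n_cpgs // 4, 1)
    genes = np.array([f"GENE{k:05d}" for k in rng.integers(0, n_genes, size=n_cpgs)],
                     dtype=object)
    genes[(rng.random(n_cpgs) < unannotated_fraction)] = ""
    ann = pd.DataFrame({
        "chrom": chrom,
        "pos": pos,
        "gene": genes,
        "promoter": rng.random(n_cpgs) < 0.3,
        "dmr": rng.random(n_cpgs) < 0.05,
        "snp": (rng.random(n_cpgs) < snp_fraction) & ~prot,
        "cross_reactive": (rng.random(n_cpgs) < cross_reactive_fraction) & ~prot,
    }, index=pd.Index(cpg_ids, name="cpg_id"))
    return ann


def generate_expression(cohort: SyntheticCohort, n_transcripts: int,
                        linked_fraction: float, seed: int,
                        link_strength: float = 0.6) -> ExpressionSet:
    """Transcript expression, a fraction of it coupled to nearby CpGs.

    Linked transcripts share a gene name with, or start within 1 Mb of, a
    designated CpG and are generated as a correlation-``link_strength``
    mixture of that CpG's standardized beta and independent noise. The rest
    is pure noise. Annotation carries gene, chromosome and start position.
    """
    rng = np.random.default_rng(seed)
    beta_df = cohort.beta.to_frame()
    clean = beta_df.ffill().bfill()  # cheap completion just for coupling
    ann = cohort.annotation
    sample_ids = list(beta_df.index)
    n_linked = int(round(linked_fraction * n_transcripts))
    tx_ids = [f"TX{k:06d}" for k in range(n_transcripts)]
    # prefer planted CpGs as link targets so enrichment has signal to find
    preferred = [c for c in cohort.truth.baseline.member_ids
                 + cohort.truth.attrition.member_ids]
    others = [c for c in beta_df.columns if c not in set(preferred)]
    targets = (preferred + list(rng.permutation(others)))[:n_linked]
    values = np.empty((len(sample_ids), n_transcripts))
    rows, linked_pairs = [], []
    for k, tx in enumerate(tx_ids):
        if k < len(targets):
            cpg = targets[k]
            x = clean[cpg].to_numpy()
            xs = (x - x.mean()) / max(x.std(ddof=1), 1e-12)
            noise = rng.standard_normal(len(sample_ids))
            values[:, k] = link_strength * xs + np.sqrt(1 - link_strength ** 2) * noise
            same_gene = bool(ann.loc[cpg, "gene"]) and rng.random() < 0.5
            if same_gene:
                gene, chrom = ann.loc[cpg, "gene"], ann.loc[cpg, "chrom"]
                start = int(rng.integers(1, 150_000_000))
            else:
                gene = f"GENE{rng.integers(50_000, 60_000):05d}"
                chrom = ann.loc[cpg, "chrom"]
                start = int(max(1, ann.loc[cpg, "pos"] + rng.integers(-900_000, 900_000)))
            linked_pairs.append((cpg, tx))
        else:
            values[:, k] = rng.standard_normal(len(sample_ids))
            gene = f"GENE{rng.integers(60_000, 70_000):05d}"
            chrom = str(rng.choice(AUTOSOMES))
            start = int(rng.integers(1, 150_000_000))
        rows.append((tx, gene, chrom, start))
    tx_ann = pd.DataFrame(rows, columns=["transcript_id", "gene", "chrom", "start"]
                          ).set_index("transcript_id")
    return ExpressionSet(values=pd.DataFrame(values, index=sample_ids, columns=tx_ids),
                         annotation=tx_ann, linked_pairs=linked_pairs)


def generate_genesets(cohort: SyntheticCohort, n_sets: int, seed: int,
                      size_range: tuple[int, int] = (5, 40)) -> dict[str, list[str]]:
    """Random gene sets over the cohort's gene universe, plus one planted set
    collecting genes of the true baseline CpGs (a positive control)."""
    rng = np.random.default_rng(seed)
    universe = sorted({g for g in cohort.annotation["gene"] if g}
                      | {g for g in cohort.expression.annotation["gene"] if g})
    sets: dict[str, list[str]] = {}
    for k in range(n_sets):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        size = min(size, len(universe))
        sets[f"PATHWAY_{k:03d}"] = sorted(rng.choice(universe, size=size, replace=False))
    truth_genes = sorted({str(cohort.annotation.loc[c, "gene"])
                          for c in cohort.truth.baseline.member_ids
                          if cohort.annotation.loc[c, "gene"]})
    if len(truth_genes) >= 3:
        sets["PATHWAY_TRUTH"] = truth_genes
    return sets


def write_cohort(cohort: SyntheticCohort, directory) -> None:
    """Write every cohort component as TSV (GMT for gene sets)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cohort.beta.to_tsv(d / "beta.tsv")
    cohort.covariates.rename_axis("sample_id").to_csv(d / "covariates.tsv", sep="\t")
    cohort.telomeres.to_tsv(d / "telomeres.tsv")
    cohort.annotation.to_csv(d / "annotation.tsv", sep="\t")
    cohort.expression.values.rename_axis("sample_id").to_csv(d / "expression.tsv", sep="\t")
    cohort.expression.annotation.to_csv(d / "transcript_annotation.tsv", sep="\t")
    with open(d / "genesets.gmt", "w") as fh:
        for name, genes in cohort.genesets.items():
            fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")
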