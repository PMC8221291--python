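"""End-to-end orchestration: QC -> attrition -> EWAS -> selection -> enrichment.

A `PipelineConfig` collects input paths and every stage parameter. The
"full" profile keeps the study-scale replicate counts (1000 stability subsamples,
10,000 bootstrap replicates); the "demo" profile shrinks them to
desk-scale (200 / 1000) for smoke runs and simulation studies. A single
root seed determines all stage seeds, and a JSON manifest written next to
the result tables fully reconstructs a run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .qc import BetaMatrix, run_qc
from .telomere import (TelomerePanel, rtm_corrected_attrition,
                       paired_difference_test, variance_homogeneity_test)
from .model import MethylomeTelomereModel, DEFAULT_COVARIATES
from .selection import PenalizedFitConfig
from .enrichment import (read_gmt, pair_cpg_transcripts, correlate_pairs,
                         query_genes_from_pairs, ora_hypergeometric)
from .simulate import SimConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "simulate_and_run", "PROFILES"]

PROFILES = {
    "full": {"b_stability": 1000, "b_bootstrap": 10000},
    "demo": {"b_stability": 200, "b_bootstrap": 1000},
}


@dataclass
class PipelineConfig:
    """Inputs and stage parameters for a full run."""

    input_dir: str = "."
    output_dir: str = "run"
    outcome: str = "baseline_tl"            # or "attrition_rate"
    profile: str = "demo"
    screen_threshold: float = 0.01
    fdr: float = 0.05
    b_stability: int | None = None          # profile default unless set
    subsample_fraction: float = 0.85
    frequency_threshold: float = 0.95
    b_bootstrap: int | None = None
    alpha_step: float = 0.05
    convergence_tol: float = 1e-4
    n_folds: int = 10
    knn_k: int = 10
    iqr_k: float = 3.0
    cis_window: int = 1_000_000
    correlation_p: float = 0.05
    seed: int = 0
    residualize: bool = False

    def selection_config(self) -> PenalizedFitConfig:
        prof = PROFILES[self.profile]
        return PenalizedFitConfig(
            alpha_step=self.alpha_step, n_folds=self.n_folds,
            convergence_tol=self.convergence_tol,
            b_stability=self.b_stability or prof["b_stability"],
            subsample_fraction=self.subsample_fraction,
            frequency_threshold=self.frequency_threshold,
            b_bootstrap=self.b_bootstrap if self.b_bootstrap is not None
            else prof["b_bootstrap"],
            seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _load_inputs(cfg: PipelineConfig):
    d = Path(cfg.input_dir)
    beta = BetaMatrix.from_tsv(d / "beta.tsv")
    covariates = pd.read_csv(d / "covariates.tsv", sep="\t", index_col=0)
    telomeres = TelomerePanel.from_tsv(d / "telomeres.tsv")
    annotation = pd.read_csv(d / "annotation.tsv", sep="\t", index_col=0)
    expression = pd.read_csv(d / "expression.tsv", sep="\t", index_col=0)
    tx_ann = pd.read_csv(d / "transcript_annotation.tsv", sep="\t", index_col=0)
    genesets = read_gmt(d / "genesets.gmt")
    return beta, covariates, telomeres, annotation, expression, tx_ann, genesets


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every stage and write result tables plus a run manifest."""
    t0 = time.time()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    beta, covariates, telomeres, annotation, expression, tx_ann, genesets = \
        _load_inputs(cfg)

    beta_qc, qc_report = run_qc(beta, annotation, knn_k=cfg.knn_k, iqr_k=cfg.iqr_k)
    with open(out / "qc_report.json", "w") as fh:
        json.dump(qc_report.to_dict(), fh, indent=1)

    attr = rtm_corrected_attrition(telomeres)
    attr.to_frame().to_csv(out / "attrition.tsv", sep="\t", index=False)
    mean_diff, t_stat, p_paired = paired_difference_test(telomeres)
    stat_var, p_var = variance_homogeneity_test(telomeres)

    if cfg.outcome == "baseline_tl":
        y = telomeres.x1
    elif cfg.outcome == "attrition_rate":
        y = attr.rate
    else:
        raise ValueError(f"unknown outcome: {cfg.outcome!r}")

    cov_cols = [c for c in DEFAULT_COVARIATES if c in covariates.columns]
    model = MethylomeTelomereModel(
        y, beta_qc, covariates=covariates.loc[beta_qc.sample_ids, cov_cols],
        config=cfg.selection_config(), screen_threshold=cfg.screen_threshold,
        residualize=cfg.residualize)
    res = model.fit()

    ewas = res.ewas_table.copy()
    ewas["chrom"] = annotation.loc[ewas.index, "chrom"].values
    ewas["pos"] = annotation.loc[ewas.index, "pos"].values
    ewas["neg_log10_p"] = -np.log10(np.maximum(ewas["p_corrected"], 1e-300))
    ewas.to_csv(out / "ewas.tsv", sep="\t")
    (out / "candidates.txt").write_text("\n".join(res.candidates) + "\n")
    chord_export(res, annotation).to_csv(out / "final_model_annotated.tsv",
                                         sep="\t", index=False)
    res.stability.frequency.to_csv(out / "stability_frequency.tsv", sep="\t")
    res.stability.records.to_csv(out / "stability_records.tsv", sep="\t")
    res.final_model.to_frame().to_csv(out / "final_model.tsv", sep="\t", index=False)
    with open(out / "summary.txt", "w") as fh:
        fh.write(res.summary() + "\n")

    sel_ann = annotation.loc[[c for c in res.final_mains]]
    pairs = pair_cpg_transcripts(sel_ann, tx_ann, window=cfg.cis_window)
    correlations = correlate_pairs(beta_qc.to_frame(), expression, pairs,
                                   p_threshold=cfg.correlation_p)
    correlations.to_csv(out / "cpg_transcript_correlations.tsv", sep="\t",
                        index=False)
    ora_query = query_genes_from_pairs(correlations, tx_ann)
    universe = sorted({str(g) for g in tx_ann["gene"] if g})
    pathway = ora_hypergeometric(
        [g for g in ora_query.query_genes if g in set(universe)],
        genesets, universe, q_threshold=cfg.fdr)
    pathway.to_csv(out / "pathways.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "seed": cfg.seed,
        "stage_counts": {
            "cpgs_after_qc": beta_qc.n_cpgs,
            "samples": beta_qc.n_samples,
            "ewas_rows": len(res.ewas_table),
            "candidates": len(res.candidates),
            "adaptive_mains": len(res.adaptive_mains),
            "final_mains": len(res.final_mains),
            "final_interactions": len(res.final_interactions),
            "pairs_tested": ora_query.n_pairs_tested,
            "pairs_significant": ora_query.n_pairs_significant,
            "transcripts_significant": ora_query.n_transcripts_significant,
        },
        "telomere_tests": {
            "paired_mean_diff": mean_diff, "paired_t": t_stat, "paired_p": p_paired,
            "variance_stat": stat_var, "variance_p": p_var,
            "rho_hat": attr.rho_hat, "theta_hat": attr.theta_hat,
        },
        "fit": {"r_pearson": res.r_pearson, "r_squared": res.rsquared},
        "runtime_s": round(time.time() - t0, 2),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out


def chord_export(res, annotation: pd.DataFrame) -> pd.DataFrame:
    """Chord-diagram-ready table: term, location, weight, EWAS coefficient,
    promoter/DMR flags. Interaction rows carry both member locations."""
    from .selection import INTERACTION_SEP, split_interaction
    rows = []
    ewas_beta = res.ewas_table["beta_m"] if "beta_m" in res.ewas_table else None

    def _ann(cpg, field, default=""):
        return annotation.loc[cpg, field] if cpg in annotation.index else default

    for term, w in res.final_model.weights.items():
        if INTERACTION_SEP in term:
            s, t = split_interaction(term)
            rows.append((term, "interaction",
                         f"{_ann(s, 'chrom')}:{_ann(t, 'chrom')}", w,
                         np.nan, False, False))
        else:
            rows.append((term, "main", str(_ann(term, "chrom")), w,
                         float(ewas_beta.get(term, np.nan))
                         if ewas_beta is not None else np.nan,
                         bool(_ann(term, "promoter", False)),
                         bool(_ann(term, "dmr", False))))
    return pd.DataFrame(rows, columns=["term", "kind", "chrom", "weight",
                                       "ewas_beta", "promoter", "dmr"])


@dataclass
class RecoveryReport:
    """Selection performance against the planted truth."""

    outcome: str
    sensitivity_mains: float
    fdp_terms: float
    r_squared: float
    target_r2: float
    selected_terms: list[str] = field(default_factory=list)
    true_mains: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def score_recovery(res, truth_outcome, target_r2: float,
                   outcome: str) -> RecoveryReport:
    """Score a fitted pipeline result against a planted outcome."""
    true_mains = set(truth_outcome.main_ids)
    truth_terms = set(truth_outcome.member_ids) | set(truth_outcome.interaction_ids)
    selected = list(res.final_model.weights.index)
    hit = sum(1 for m in true_mains
              if m in set(res.final_mains))
    sens = hit / len(true_mains) if true_mains else float("nan")
    false = sum(1 for t in selected if t not in truth_terms)
    fdp = false / len(selected) if selected else 0.0
    return RecoveryReport(outcome=outcome, sensitivity_mains=sens, fdp_terms=fdp,
                          r_squared=res.rsquared, target_r2=target_r2,
                          selected_terms=selected, true_mains=sorted(true_mains))


def simulate_and_run(sim_config: SimConfig, outcome: str = "baseline_tl",
                     selection_config: PenalizedFitConfig | None = None,
                     compute_bootstrap: bool = False) -> RecoveryReport:
    """Generate a cohort, QC it, fit the pipeline model, score the truth."""
    cohort = generate_cohort(sim_config)
    beta_qc, _ = run_qc(cohort.beta, cohort.annotation)
    cfg = selection_config or PenalizedFitConfig(
        b_stability=PROFILES["demo"]["b_stability"],
        b_bootstrap=PROFILES["demo"]["b_bootstrap"], seed=sim_config.seed)
    model = MethylomeTelomereModel.from_cohort(cohort, outcome=outcome, config=cfg)
    cov = model.covariates
    model = MethylomeTelomereModel(model.endog, beta_qc, covariates=cov,
                                   config=cfg,
                                   screen_threshold=model.screen_threshold)
    res = model.fit(compute_bootstrap=compute_bootstrap)
    truth = (cohort.truth.baseline if outcome == "baseline_tl"
             else cohort.truth.attrition)
    return score_recovery(res, truth, sim_config.target_r2, outcome)


def simulate_to_dir(sim_config: SimConfig, directory) -> Path:
    cohort = generate_cohort(sim_config)
    write_cohort(cohort, directory)
    return Path(directory)
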