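"""Methylation beta-value construction and quality control.

The QC chain mirrors a standard Illumina EPIC workflow downstream of
normalization: call-rate filtering on detection p-values, K-nearest-neighbour
imputation of missing beta values, per-CpG outlier trimming at 3 IQR beyond
the quartiles, and removal of sex-chromosome, SNP-overlapping and
cross-reactive probes. Normalization, batch correction and cell-type
deconvolution are upstream concerns: this module consumes their outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BetaMatrix",
    "QcReport",
    "beta_from_intensities",
    "filter_call_rates",
    "trim_outliers_iqr",
    "knn_impute",
    "filter_probes",
    "run_qc",
]


@dataclass
class BetaMatrix:
    """Samples x CpGs methylation fractions in [0, 1], NaN for missing."""

    values: np.ndarray
    sample_ids: list[str]
    cpg_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("beta matrix must be 2-D (samples x CpGs)")
        if self.values.shape != (len(self.sample_ids), len(self.cpg_ids)):
            raise ValueError("beta matrix shape does not match id lists")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise ValueError("duplicate CpG ids")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.cpg_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BetaMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)),
                   list(df.columns.astype(str)))

    @classmethod
    def from_tsv(cls, path) -> "BetaMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def select_cpgs(self, keep: list[str]) -> "BetaMatrix":
        idx = [self.cpg_ids.index(c) for c in keep]
        return BetaMatrix(self.values[:, idx], list(self.sample_ids), list(keep))


@dataclass
class QcReport:
    """Per-stage accounting of removed probes/samples and modified cells."""

    probes_removed_by: dict[str, int] = field(default_factory=dict)
    samples_removed: list[str] = field(default_factory=list)
    cells_trimmed: int = 0
    cells_imputed: int = 0
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "probes_removed_by": dict(self.probes_removed_by),
            "samples_removed": list(self.samples_removed),
            "cells_trimmed": int(self.cells_trimmed),
            "cells_imputed": int(self.cells_imputed),
            "notes": list(self.notes),
        }


def read_exclusion_list(path) -> set[str]:
    """Probe exclusion list: one CpG id per line, blanks ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def beta_from_intensities(M: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Beta = M / (M + U) elementwise; zero total intensity yields NaN."""
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if M.shape != U.shape:
        raise ValueError("M and U must have the same shape")
    if np.nanmin(M) < 0 or np.nanmin(U) < 0:
        raise ValueError("negative intensities are not allowed")
    total = M + U
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, M / total, np.nan)
    return beta


def filter_call_rates(detection_p: pd.DataFrame,
                      probe_threshold: float = 0.95,
                      sample_threshold: float = 0.98,
                      detection_alpha: float = 1e-16,
                      ) -> tuple[list[str], list[str], QcReport]:
    """Call-rate filtering from a samples x CpGs detection p-value matrix.

    A cell is "detected" iff its detection p-value is <= ``detection_alpha``.
    Probes detected in fewer than ``probe_threshold`` of samples are dropped
    first; then samples detected in fewer than ``sample_threshold`` of the
    remaining probes are dropped.
    """
    vals = detection_p.to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("detection p-values must lie in [0, 1]")
    detected = vals <= detection_alpha
    probe_rate = detected.mean(axis=0)
    keep_probes_mask = probe_rate >= probe_threshold
    kept_probes = [c for c, k in zip(detection_p.columns, keep_probes_mask) if k]
    if not kept_probes:
        raise ValueError("call-rate filtering removed every probe")
    sample_rate = detected[:, keep_probes_mask].mean(axis=1)
    keep_samples_mask = sample_rate >= sample_threshold
    kept_samples = [s for s, k in zip(detection_p.index, keep_samples_mask) if k]
    if not kept_samples:
        raise ValueError("call-rate filtering removed every sample")
    report = QcReport(
        probes_removed_by={"call_rate": int((~keep_probes_mask).sum())},
        samples_removed=[str(s) for s, k in zip(detection_p.index, keep_samples_mask) if not k],
    )
    return [str(c) for c in kept_probes], [str(s) for s in kept_samples], report


def trim_outliers_iqr(beta: BetaMatrix, k: float = 3.0) -> tuple[BetaMatrix, int]:
    """Set per-CpG values strictly beyond Q1 - k*IQR or Q3 + k*IQR to missing.

    Quartiles use linear interpolation (numpy default, R type 7); the trimming
    outcome depends on this choice so it is fixed here. Returns the trimmed
    matrix and the number of cells set to missing. Idempotent only in the
    sense of a single pass: callers wanting a fixed point re-apply.
    """
    vals = beta.values.copy()
    n_obs = np.sum(np.isfinite(vals), axis=0)
    if np.any(n_obs == 0):
        bad = [beta.cpg_ids[j] for j in np.where(n_obs == 0)[0]]
        raise ValueError(f"all-missing CpGs: {bad[:5]}")
    q1 = np.nanquantile(vals, 0.25, axis=0)
    q3 = np.nanquantile(vals, 0.75, axis=0)
    iqr = q3 - q1
    lo = q1 - k * iqr
    hi = q3 + k * iqr
    with np.errstate(invalid="ignore"):
        outlier = (vals < lo) | (vals > hi)
    outlier &= np.isfinite(vals)
    vals[outlier] = np.nan
    return BetaMatrix(vals, list(beta.sample_ids), list(beta.cpg_ids)), int(outlier.sum())


def knn_impute(beta: BetaMatrix, k: int = 10) -> tuple[BetaMatrix, int]:
    """Impute missing entries from the k nearest CpGs.

    Distances between CpG columns are Euclidean on a mean-completed copy of
    the matrix (the standard fast approximation to pairwise-complete
    distances). A missing entry is filled with the mean of the k nearest
    CpGs that are observed for that sample; if none are (or the CpG has no
    neighbours), it falls back to the CpG mean, logged. Observed values are
    never modified, and the output respects [0, 1].

    The p x p distance matrix makes this quadratic in the number of CpGs —
    fine at the panel sizes this pipeline targets.
    """
    vals = beta.values.copy()
    missing = ~np.isfinite(vals)
    n_missing = int(missing.sum())
    if n_missing == 0:
        return BetaMatrix(vals, list(beta.sample_ids), list(beta.cpg_ids)), 0
    col_means = np.nanmean(vals, axis=0)
    if np.any(~np.isfinite(col_means)):
        bad = [beta.cpg_ids[j] for j in np.where(~np.isfinite(col_means))[0]]
        raise ValueError(f"all-missing CpGs cannot be imputed: {bad[:5]}")
    filled = np.where(missing, col_means[None, :], vals)
    sq = np.einsum("ij,ij->j", filled, filled)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (filled.T @ filled)
    np.fill_diagonal(d2, np.inf)
    n_fallback = 0
    for j in np.where(missing.any(axis=0))[0]:
        order = np.argsort(d2[j], kind="stable")
        for i in np.where(missing[:, j])[0]:
            donors = order[~missing[i, order]][:k]
            if donors.size:
                vals[i, j] = vals[i, donors].mean()
            else:
                vals[i, j] = col_means[j]
                n_fallback += 1
    if n_fallback:
        logger.info("%d cells had no observed neighbours; CpG-mean imputed",
                    n_fallback)
    vals = np.clip(vals, 0.0, 1.0)
    return BetaMatrix(vals, list(beta.sample_ids), list(beta.cpg_ids)), n_missing


def filter_probes(beta: BetaMatrix, annotation: pd.DataFrame,
                  extra_exclusions: set[str] | None = None) -> tuple[BetaMatrix, QcReport]:
    """Drop X/Y-chromosome, SNP-overlapping and cross-reactive probes.

    ``annotation`` is indexed by CpG id with columns ``chrom`` and boolean
    ``snp`` and ``cross_reactive`` flags; it must cover every CpG in the
    matrix. Column order of the survivors is preserved.
    """
    missing_ann = [c for c in beta.cpg_ids if c not in annotation.index]
    if missing_ann:
        raise ValueError(f"unannotated CpGs: {missing_ann[:10]}")
    ann = annotation.loc[beta.cpg_ids]
    chrom = ann["chrom"].astype(str)
    on_xy = chrom.isin({"X", "Y", "chrX", "chrY"}).to_numpy()
    snp = ann["snp"].astype(bool).to_numpy() if "snp" in ann else np.zeros(len(ann), bool)
    xr = (ann["cross_reactive"].astype(bool).to_numpy()
          if "cross_reactive" in ann else np.zeros(len(ann), bool))
    extra = np.array([c in extra_exclusions for c in beta.cpg_ids], bool) \
        if extra_exclusions else np.zeros(len(beta.cpg_ids), bool)
    drop = on_xy | snp | xr | extra
    keep = [c for c, d in zip(beta.cpg_ids, drop) if not d]
    report = QcReport(probes_removed_by={
        "xy_chromosome": int(on_xy.sum()),
        "snp": int((snp & ~on_xy).sum()),
        "cross_reactive": int((xr & ~on_xy & ~snp).sum()),
        "extra_list": int((extra & ~on_xy & ~snp & ~xr).sum()),
        "total": int(drop.sum()),
    })
    filtered = BetaMatrix(beta.values[:, ~drop], list(beta.sample_ids), keep)
    return filtered, report


def run_qc(beta: BetaMatrix, annotation: pd.DataFrame,
           detection_p: pd.DataFrame | None = None,
           knn_k: int = 10, iqr_k: float = 3.0,
           extra_exclusions: set[str] | None = None,
           ) -> tuple[BetaMatrix, QcReport]:
    """Full QC chain: call rates -> KNN imputation -> IQR trim -> probe filters.

    Trimming after imputation re-introduces missingness; those cells are then
    re-completed by CpG-mean imputation (logged in the report) so downstream
    stages always see a complete matrix.
    """
    report = QcReport()
    if detection_p is not None:
        kept_probes, kept_samples, cr = filter_call_rates(detection_p)
        report.probes_removed_by.update(cr.probes_removed_by)
        report.samples_removed = cr.samples_removed
        keep_s = [i for i, s in enumerate(beta.sample_ids) if s in set(kept_samples)]
        keep_c = [j for j, c in enumerate(beta.cpg_ids) if c in set(kept_probes)]
        beta = BetaMatrix(beta.values[np.ix_(keep_s, keep_c)],
                          [beta.sample_ids[i] for i in keep_s],
                          [beta.cpg_ids[j] for j in keep_c])
    beta, n_imp = knn_impute(beta, k=knn_k)
    report.cells_imputed = n_imp
    beta, n_trim = trim_outliers_iqr(beta, k=iqr_k)
    report.cells_trimmed = n_trim
    if n_trim:
        # re-complete trimmed cells with the CpG mean so the matrix is dense
        vals = beta.values.copy()
        col_means = np.nanmean(vals, axis=0)
        rr, cc = np.where(~np.isfinite(vals))
        vals[rr, cc] = col_means[cc]
        beta = BetaMatrix(vals, list(beta.sample_ids), list(beta.cpg_ids))
        report.notes.append(f"re-imputed {n_trim} trimmed cells by CpG mean")
    beta, pf = filter_probes(beta, annotation, extra_exclusions)
    report.probes_removed_by.update(pf.probes_removed_by)
    return beta, report
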