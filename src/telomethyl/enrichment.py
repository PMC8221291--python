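"""CpG-to-transcript correlation mapping and pathway over-representation.

Selected CpGs are linked to transcripts either by shared gene symbol or by
genomic proximity (transcript start within 1 Mb of the CpG, same
chromosome). Surviving Pearson-correlated pairs (p < 0.05) supply the query
gene list for a hypergeometric over-representation analysis against GMT
gene sets; a pathway is significant when its BH q-value is below 0.05 AND
at least 3 query genes fall in it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "read_gmt",
    "write_gmt",
    "pair_cpg_transcripts",
    "correlate_pairs",
    "ora_hypergeometric",
]

CIS_WINDOW = 1_000_000


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: name TAB description TAB gene TAB gene ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description] + list(genes)) + "\n")


def pair_cpg_transcripts(cpg_annotation: pd.DataFrame,
                         transcript_annotation: pd.DataFrame,
                         window: int = CIS_WINDOW) -> pd.DataFrame:
    """Candidate CpG-transcript pairs by shared gene or cis proximity.

    Same-gene pairs match on case-insensitive gene symbol regardless of
    location; cis pairs require the same chromosome and a transcript start
    within ``window`` bases of the CpG position (closed interval). The union
    is deduplicated; each pair keeps its link type (``same_gene`` wins when
    both rules apply). Unannotated CpGs contribute cis pairs only.
    """
    rows = []
    tx = transcript_annotation.copy()
    tx["_gene_norm"] = tx["gene"].astype(str).str.upper()
    for cpg, c in cpg_annotation.iterrows():
        gene = str(c.get("gene", "") or "").upper()
        for txid, t in tx.iterrows():
            same_gene = bool(gene) and t["_gene_norm"] == gene and gene != "NAN"
            cis = (str(t["chrom"]) == str(c["chrom"])
                   and abs(int(t["start"]) - int(c["pos"])) <= window)
            if same_gene or cis:
                rows.append((str(cpg), str(txid),
                             "same_gene" if same_gene else "cis_window"))
    pairs = pd.DataFrame(rows, columns=["cpg_id", "transcript_id", "link_type"])
    pairs = pairs.drop_duplicates(subset=["cpg_id", "transcript_id"])
    return pairs.reset_index(drop=True)


def correlate_pairs(beta_df: pd.DataFrame, expression: pd.DataFrame,
                    pairs: pd.DataFrame, p_threshold: float = 0.05,
                    ) -> pd.DataFrame:
    """Pearson correlation within each pair on shared complete samples.

    Returns all computed pairs with r, two-sided p and a ``significant``
    flag (p < threshold). Constant vectors and pairs with fewer than 4
    shared samples are skipped and logged.
    """
    shared = beta_df.index.intersection(expression.index)
    rows = []
    for _, row in pairs.iterrows():
        cpg, txid = row["cpg_id"], row["transcript_id"]
        if cpg not in beta_df.columns or txid not in expression.columns:
            continue
        x = beta_df.loc[shared, cpg].to_numpy(float)
        yv = expression.loc[shared, txid].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(yv)
        if ok.sum() < 4:
            logger.info("pair (%s, %s): <4 shared samples, skipped", cpg, txid)
            continue
        if x[ok].std() == 0 or yv[ok].std() == 0:
            logger.info("pair (%s, %s): constant vector, skipped", cpg, txid)
            continue
        r, p = stats.pearsonr(x[ok], yv[ok])
        rows.append((cpg, txid, row["link_type"], float(r), float(p)))
    out = pd.DataFrame(rows, columns=["cpg_id", "transcript_id", "link_type",
                                      "r_pearson", "p_value"])
    out["significant"] = out["p_value"] < p_threshold
    return out


@dataclass
class OraSummary:
    n_pairs_tested: int
    n_pairs_significant: int
    n_transcripts_significant: int
    query_genes: list[str]


def query_genes_from_pairs(correlations: pd.DataFrame,
                           transcript_annotation: pd.DataFrame) -> OraSummary:
    """Gene symbols of significantly correlated transcripts (the ORA query).

    Pair counts and distinct-transcript counts can differ (one transcript may
    correlate with several CpGs); both are reported.
    """
    sig = correlations[correlations["significant"]]
    tx = sig["transcript_id"].unique()
    genes = sorted({str(g) for g in transcript_annotation.loc[
        transcript_annotation.index.intersection(tx), "gene"] if g})
    return OraSummary(n_pairs_tested=len(correlations),
                      n_pairs_significant=int(sig.shape[0]),
                      n_transcripts_significant=len(tx),
                      query_genes=genes)


def ora_hypergeometric(query_genes: list[str], genesets: dict[str, list[str]],
                       universe: list[str], q_threshold: float = 0.05,
                       min_genes: int = 3) -> pd.DataFrame:
    """Hypergeometric over-representation of query genes in each gene set.

    Gene sets are intersected with the universe; the upper-tail p is
    P(overlap >= observed) for drawing |query| genes from the universe.
    Significance requires BH q < ``q_threshold`` AND overlap >= ``min_genes``
    (both boundaries strict/inclusive exactly as stated).
    """
    uni = sorted({str(g).upper() for g in universe if g})
    query = sorted({str(g).upper() for g in query_genes if g})
    if not set(query) <= set(uni):
        raise ValueError("query genes must be contained in the universe")
    if not query:
        logger.warning("empty query gene list: no enrichment computed")
        return pd.DataFrame(columns=["pathway_id", "gene_count_in_query",
                                     "pathway_size", "gene_ratio",
                                     "p_hypergeometric", "q_bh", "significant"])
    M, N = len(uni), len(query)
    rows = []
    for name, genes in genesets.items():
        gs = {str(g).upper() for g in genes} & set(uni)
        K = len(gs)
        if K == 0:
            continue
        k = len(gs & set(query))
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        rows.append((name, k, K, k / K, p))
    out = pd.DataFrame(rows, columns=["pathway_id", "gene_count_in_query",
                                      "pathway_size", "gene_ratio",
                                      "p_hypergeometric"])
    out["q_bh"] = bh_adjust(out["p_hypergeometric"].to_numpy()) if len(out) else []
    out["significant"] = (out["q_bh"] < q_threshold) & \
        (out["gene_count_in_query"] >= min_genes)
    return out.sort_values("p_hypergeometric").reset_index(drop=True)
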