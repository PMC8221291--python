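"""CpG-transcript pairing, correlation screening, and pathway ORA."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from telomethyl.enrichment import (read_gmt, write_gmt, pair_cpg_transcripts,
                                   correlate_pairs, ora_hypergeometric,
                                   query_genes_from_pairs)


def _cpg_ann(rows):
    return pd.DataFrame(rows, columns=["cpg_id", "chrom", "pos", "gene"]
                        ).set_index("cpg_id")


def _tx_ann(rows):
    return pd.DataFrame(rows, columns=["transcript_id", "gene", "chrom", "start"]
                        ).set_index("transcript_id")


class TestPairing:
    def test_cis_window_boundary(self):
        cpgs = _cpg_ann([("cg1", "1", 5_000_000, "")])
        txs = _tx_ann([("t1", "G1", "1", 5_900_000),
                       ("t2", "G2", "1", 6_100_000),
                       ("t3", "G3", "1", 6_000_000)])  # exactly 1 Mb: included
        pairs = pair_cpg_transcripts(cpgs, txs)
        assert set(pairs["transcript_id"]) == {"t1", "t3"}

    def test_same_gene_pairs_across_chromosomes(self):
        cpgs = _cpg_ann([("cg1", "1", 100, "ABC")])
        txs = _tx_ann([("t1", "abc", "7", 999)])  # case-insensitive match
        pairs = pair_cpg_transcripts(cpgs, txs)
        assert len(pairs) == 1
        assert pairs.iloc[0]["link_type"] == "same_gene"

    def test_hand_enumerated_fixture(self):
        cpgs = _cpg_ann([("cg1", "1", 1_000_000, "G1"),
                         ("cg2", "2", 5_000_000, "G2"),
                         ("cg3", "3", 9_000_000, "")])
        txs = _tx_ann([("t1", "G1", "5", 1),        # same gene as cg1
                       ("t2", "G2", "2", 5_500_000),  # same gene AND cis to cg2
                       ("t3", "X9", "1", 1_500_000),  # cis to cg1
                       ("t4", "X8", "3", 9_999_999),  # cis to cg3
                       ("t5", "X7", "3", 11_000_000)])  # 2 Mb away: no pair
        pairs = pair_cpg_transcripts(cpgs, txs)
        expected = {("cg1", "t1"), ("cg2", "t2"), ("cg1", "t3"), ("cg3", "t4")}
        assert set(map(tuple, pairs[["cpg_id", "transcript_id"]].values)) == expected
        # dual-rule pair is deduplicated and labelled same_gene
        assert pairs.set_index(["cpg_id", "transcript_id"]).loc[
            ("cg2", "t2"), "link_type"] == "same_gene"


class TestCorrelation:
    def test_exact_copy_has_unit_correlation(self, rng):
        beta = pd.DataFrame({"cg1": rng.uniform(0.2, 0.8, 30)},
                            index=[f"S{i}" for i in range(30)])
        expr = pd.DataFrame({"t1": beta["cg1"].to_numpy()}, index=beta.index)
        pairs = pd.DataFrame({"cpg_id": ["cg1"], "transcript_id": ["t1"],
                              "link_type": ["same_gene"]})
        out = correlate_pairs(beta, expr, pairs)
        assert out.iloc[0]["r_pearson"] == pytest.approx(1.0)
        assert out.iloc[0]["significant"]

    def test_null_pairs_survive_at_nominal_rate(self, rng):
        n, m = 60, 300
        beta = pd.DataFrame(rng.uniform(0, 1, (n, m)),
                            index=[f"S{i}" for i in range(n)],
                            columns=[f"cg{j}" for j in range(m)])
        expr = pd.DataFrame(rng.standard_normal((n, m)), index=beta.index,
                            columns=[f"t{j}" for j in range(m)])
        pairs = pd.DataFrame({"cpg_id": beta.columns, "transcript_id": expr.columns,
                              "link_type": "cis_window"})
        out = correlate_pairs(beta, expr, pairs)
        assert out["significant"].mean() == pytest.approx(0.05, abs=0.035)

    def test_constant_vector_skipped(self, rng):
        beta = pd.DataFrame({"cg1": np.full(10, 0.5)},
                            index=[f"S{i}" for i in range(10)])
        expr = pd.DataFrame({"t1": rng.standard_normal(10)}, index=beta.index)
        pairs = pd.DataFrame({"cpg_id": ["cg1"], "transcript_id": ["t1"],
                              "link_type": ["cis_window"]})
        assert len(correlate_pairs(beta, expr, pairs)) == 0

    def test_pair_and_transcript_counts_both_reported(self, rng):
        # two CpGs correlated with the same transcript: 2 pairs, 1 transcript
        x = rng.uniform(0.2, 0.8, 40)
        beta = pd.DataFrame({"cg1": x, "cg2": x + rng.normal(0, 0.01, 40)},
                            index=[f"S{i}" for i in range(40)])
        expr = pd.DataFrame({"t1": x}, index=beta.index)
        tx_ann = _tx_ann([("t1", "G1", "1", 500)])
        pairs = pd.DataFrame({"cpg_id": ["cg1", "cg2"],
                              "transcript_id": ["t1", "t1"],
                              "link_type": "same_gene"})
        out = correlate_pairs(beta, expr, pairs)
        summary = query_genes_from_pairs(out, tx_ann)
        assert summary.n_pairs_significant == 2
        assert summary.n_transcripts_significant == 1
        assert summary.query_genes == ["G1"]


def _enumerated_upper_tail(universe_size, pathway_size, query_size, observed):
    """Exhaustive enumeration of query draws; exact upper-tail probability."""
    universe = range(universe_size)
    pathway = set(range(pathway_size))
    total = hits = 0
    for draw in combinations(universe, query_size):
        total += 1
        hits += len(pathway & set(draw)) >= observed
    return hits / total


class TestHypergeometricOra:
    def test_full_overlap_matches_exact_combinatorics(self):
        universe = [f"G{i}" for i in range(20)]
        genesets = {"P": universe[:5]}
        out = ora_hypergeometric(universe[:5], genesets, universe)
        assert out.iloc[0]["p_hypergeometric"] == pytest.approx(1 / 15504, rel=1e-9)

    @pytest.mark.parametrize("m,k,q,obs", [(12, 4, 5, 2), (15, 6, 4, 1),
                                           (20, 5, 5, 3), (10, 3, 3, 0)])
    def test_matches_enumeration_on_small_universes(self, m, k, q, obs):
        universe = [f"G{i}" for i in range(m)]
        genesets = {"P": universe[:k]}
        query = universe[:obs] + universe[k:k + (q - obs)]
        out = ora_hypergeometric(query, genesets, universe)
        assert out.iloc[0]["gene_count_in_query"] == obs
        expected = _enumerated_upper_tail(m, k, q, obs)
        assert out.iloc[0]["p_hypergeometric"] == pytest.approx(expected, rel=1e-9)

    def test_zero_overlap_and_query_equals_universe(self):
        universe = [f"G{i}" for i in range(10)]
        gs = {"P": universe[:4]}
        none = ora_hypergeometric(universe[4:7], gs, universe)
        assert none.iloc[0]["p_hypergeometric"] == pytest.approx(1.0)
        everything = ora_hypergeometric(universe, gs, universe)
        assert everything.iloc[0]["p_hypergeometric"] == pytest.approx(1.0)
        assert everything.iloc[0]["gene_count_in_query"] == 4

    def test_two_condition_significance_rule_boundaries(self):
        universe = [f"G{i}" for i in range(400)]
        # strong overlap but only 2 genes: must NOT be significant
        gs = {"TWO": universe[:2], "FOUR": universe[:4]}
        out = ora_hypergeometric(universe[:4], gs, universe).set_index("pathway_id")
        assert not out.loc["TWO", "significant"]
        assert out.loc["FOUR", "significant"]
        assert out.loc["FOUR", "gene_ratio"] == pytest.approx(1.0)

    def test_invariant_to_ordering_and_duplicates(self):
        universe = [f"G{i}" for i in range(30)]
        gs = {"P": universe[:6] + universe[:2]}  # duplicated members
        a = ora_hypergeometric(universe[:5], gs, universe)
        b = ora_hypergeometric(universe[:5][::-1] + universe[:1], gs, universe[::-1])
        assert a.iloc[0]["p_hypergeometric"] == pytest.approx(
            b.iloc[0]["p_hypergeometric"])
        assert a.iloc[0]["pathway_size"] == 6

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            ora_hypergeometric(["NOPE"], {"P": ["G1"]}, ["G1", "G2"])

    def test_empty_query_warns_and_returns_empty(self):
        out = ora_hypergeometric([], {"P": ["G1"]}, ["G1"])
        assert out.empty


def test_gmt_round_trip(tmp_path):
    sets = {"A": ["G1", "G2", "G3"], "B": ["G9"]}
    write_gmt(sets, tmp_path / "x.gmt")
    assert read_gmt(tmp_path / "x.gmt") == sets
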