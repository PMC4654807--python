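"""lncRNA characterization: biotypes, co-expression, GO enrichment (classic
and elim), term attribution, pair trend."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import make_annotation
from thlineage.errors import ValidationError
from thlineage.lncfun import (
    attribute_terms_to_lncrnas,
    classify_biotype,
    coexpression_network,
    fisher_upper_tail,
    go_enrichment,
    pair_correlation_trend,
    propagate_annotations,
    validate_dag,
)


def chain_dag():
    """root <- A <- B."""
    dag = nx.DiGraph()
    dag.add_edge("A", "root")
    dag.add_edge("B", "A")
    return dag


class TestBiotypes:
    def test_single_category(self):
        ann = make_annotation(
            [(f"L{i}", "chr1", i * 100, i * 100 + 50, "+", "antisense") for i in range(4)]
        )
        tally = classify_biotype([f"L{i}" for i in range(4)], ann)
        assert tally.to_dict() == {"antisense": 4}

    def test_unknown_pooled_as_other_and_empty(self):
        ann = make_annotation(
            [("L0", "chr1", 0, 50, "+", "lincRNA"), ("L1", "chr1", 100, 150, "+", "weird")]
        )
        tally = classify_biotype(["L0", "L1"], ann)
        assert tally.to_dict() == {"lincRNA": 1, "other": 1}
        assert classify_biotype([], ann).empty

    def test_matches_generator_proportions(self, small_dataset):
        data = small_dataset
        tally = classify_biotype(list(data.lncrnas["gene_id"]), data.annotation)
        counts = data.lncrnas["biotype"].value_counts()
        for biotype, n in counts.items():
            assert tally[biotype] == n


class TestCoexpression:
    def _expr(self, rows, ids):
        return pd.DataFrame(rows, index=ids, columns=[f"s{i}" for i in range(len(rows[0]))])

    def test_affine_copy_gives_r_one(self):
        x = [1.0, 2.0, 5.0, 3.0]
        lnc = self._expr([x], ["L"])
        gene = self._expr([[2 * v + 1 for v in x]], ["G"])
        edges = coexpression_network(lnc, gene)
        assert len(edges) == 1
        assert edges["r"].iloc[0] == pytest.approx(1.0)

    def test_negated_profile_passes_absolute_threshold(self):
        x = [1.0, 2.0, 5.0, 3.0]
        edges = coexpression_network(
            self._expr([x], ["L"]), self._expr([[-v for v in x]], ["G"])
        )
        assert edges["r"].iloc[0] == pytest.approx(-1.0)

    def test_hand_computed_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        edges = coexpression_network(
            self._expr([x], ["L"]), self._expr([y], ["G"]), threshold=0.0
        )
        assert edges["r"].iloc[0] == pytest.approx(r_hand, abs=1e-12)

    def test_constant_rows_warn_and_yield_no_edges(self):
        lnc = self._expr([[3.0, 3.0, 3.0, 3.0]], ["L"])
        gene = self._expr([[1.0, 2.0, 3.0, 4.0]], ["G"])
        with pytest.warns(UserWarning, match="constant"):
            edges = coexpression_network(lnc, gene, threshold=0.0)
        assert edges.empty

    def test_threshold_strictness_around_borderline_pair(self):
        # perturbing the threshold by +/-eps around |r| flips edge membership
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = x + rng.normal(0, 1.0, size=6)
            r = abs(np.corrcoef(x, y)[0, 1])
            lnc, gene = self._expr([x], ["L"]), self._expr([y], ["G"])
            assert coexpression_network(lnc, gene, threshold=r + 1e-9).empty
            assert len(coexpression_network(lnc, gene, threshold=r - 1e-9)) == 1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            coexpression_network(
                self._expr([[1, 2]], ["L"]), self._expr([[1, 2]], ["G"])
            )


class TestGOEnrichment:
    def test_classic_exact_worked_case(self):
        # universe 20, term annotates 5, study of 5 overlaps 4:
        # p = [C(5,4)C(15,1)+C(5,5)C(15,0)]/C(20,5) = 76/15504
        universe = {f"g{i}" for i in range(20)}
        term_genes = {f"g{i}" for i in range(5)}
        study = {"g0", "g1", "g2", "g3", "g10"}
        dag = nx.DiGraph()
        dag.add_edge("T", "root")
        gene2terms = {g: {"T"} for g in term_genes}
        res = go_enrichment(study, universe, gene2terms, dag, algorithm="classic")
        row = res[res["term_id"] == "T"].iloc[0]
        assert row["pvalue"] == pytest.approx(76 / 15504, abs=1e-12)
        assert row["study_count"] == 4 and row["term_universe_count"] == 5

    def test_fisher_matches_enumeration_small_universes(self):
        from math import comb

        for N in (8, 12, 20, 30):
            for K in (2, N // 3, N // 2):
                for n in (2, N // 4, N // 2):
                    for k in range(0, min(K, n) + 1):
                        exact = sum(
                            comb(K, j) * comb(N - K, n - j)
                            for j in range(k, min(K, n) + 1)
                        ) / comb(N, n)
                        assert fisher_upper_tail(k, K, n, N) == pytest.approx(
                            exact, abs=1e-12
                        )

    def test_elim_noop_equals_classic(self):
        rng = np.random.default_rng(2)
        dag = chain_dag()
        universe = {f"g{i}" for i in range(30)}
        gene2terms = {}
        for g in rng.choice(sorted(universe), size=10, replace=False):
            gene2terms.setdefault(g, set()).add("B")
        for g in rng.choice(sorted(universe), size=8, replace=False):
            gene2terms.setdefault(g, set()).add("A")
        study = set(rng.choice(sorted(universe), size=10, replace=False))
        classic = go_enrichment(study, universe, gene2terms, dag, algorithm="classic")
        elim = go_enrichment(study, universe, gene2terms, dag, algorithm="elim", alpha_elim=0.0)
        merged = classic.merge(elim, on="term_id", suffixes=("_c", "_e"))
        np.testing.assert_allclose(merged["pvalue_c"], merged["pvalue_e"], atol=1e-15)

    def test_elim_hand_worked_chain(self):
        """B significant: its genes are removed from A (and root) before those
        are tested; A's p must match the hand-built reduced 2x2 table."""
        universe = {f"g{i}" for i in range(20)}
        b_genes = {"g0", "g1", "g2", "g3"}
        a_only = {"g4", "g5", "g6"}
        gene2terms = {g: {"B"} for g in b_genes}
        gene2terms.update({g: {"A"} for g in a_only})
        study = {"g0", "g1", "g2", "g3", "g4"}
        res = go_enrichment(
            study, universe, gene2terms, chain_dag(), algorithm="elim", alpha_elim=0.05
        )
        p_b = fisher_upper_tail(4, 4, 5, 20)
        assert p_b < 0.05  # B is eliminated
        assert res.set_index("term_id").loc["B", "pvalue"] == pytest.approx(p_b, abs=1e-12)
        # A after elimination annotates only its own 3 genes, study overlap 1
        p_a_reduced = fisher_upper_tail(1, 3, 5, 20)
        assert res.set_index("term_id").loc["A", "pvalue"] == pytest.approx(
            p_a_reduced, abs=1e-12
        )

    def test_true_path_propagation_supersets_children(self, small_dataset):
        data = small_dataset
        term_genes = propagate_annotations(data.gene2terms, data.go_dag)
        root = validate_dag(data.go_dag)
        annotated = set().union(*data.gene2terms.values())
        for child, parent in data.go_dag.edges():
            assert term_genes[child] <= term_genes[parent]
        assert term_genes[root] == {
            g for g, ts in data.gene2terms.items() if ts & set(data.go_dag.nodes)
        }

    def test_cyclic_dag_rejected(self):
        dag = nx.DiGraph([("A", "B"), ("B", "A")])
        with pytest.raises(ValidationError):
            go_enrichment(set(), {"g"}, {}, dag)


class TestAttribution:
    def test_no_edges_no_terms_and_strict_cutoff(self):
        universe = {f"g{i}" for i in range(20)}
        gene2terms = {f"g{i}": {"T"} for i in range(5)}
        dag = nx.DiGraph([("T", "root")])
        empty = attribute_terms_to_lncrnas(
            pd.DataFrame(columns=["lncrna_id", "gene_id", "r"]), universe, gene2terms, dag
        )
        assert empty.empty
        edges = pd.DataFrame({"lncrna_id": ["L"] * 4, "gene_id": [f"g{i}" for i in range(4)], "r": 0.95})
        p = fisher_upper_tail(4, 5, 4, 20)
        attr = attribute_terms_to_lncrnas(edges, universe, gene2terms, dag, cutoff=p)
        assert attr.empty  # p == cutoff excluded (strict <)
        attr2 = attribute_terms_to_lncrnas(edges, universe, gene2terms, dag, cutoff=p * 1.01)
        assert list(attr2["term_id"]) == ["T"]


class TestPairTrend:
    def test_identical_profiles_r_one(self):
        expr = pd.DataFrame([[1.0, 2, 3, 4]], index=["X"], columns=list("abcd"))
        pairs = pd.DataFrame({"lncrna_id": ["X"], "gene_id": ["X"]})
        trend, summary = pair_correlation_trend(pairs, expr, expr)
        assert trend["r"].iloc[0] == pytest.approx(1.0)
        assert summary["fraction_positive"] == 1.0

    def test_empty_pairs_no_error(self):
        expr = pd.DataFrame([[1.0, 2, 3]], index=["X"], columns=list("abc"))
        trend, summary = pair_correlation_trend(
            pd.DataFrame(columns=["lncrna_id", "gene_id"]), expr, expr
        )
        assert trend.empty and summary["n_pairs"] == 0

    def test_planted_coupling_positive_trend(self, small_dataset):
        """Planted vicinity pairs share their lineage effect sign, so the
        cross-sample correlation is strongly positive."""
        from thlineage import diffexpr

        data = small_dataset
        counts = next(m for m in data.matrices if m.platform_kind == "count")
        vst = diffexpr.variance_stabilize(
            counts.values, diffexpr.median_of_ratios_size_factors(counts.values)
        )
        pairs = pd.DataFrame(
            sorted(data.truth.vicinity_pairs), columns=["lncrna_id", "gene_id"]
        )
        trend, summary = pair_correlation_trend(pairs, vst, vst)
        assert summary["mean_r"] > 0
        assert summary["fraction_positive"] > 0.8
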