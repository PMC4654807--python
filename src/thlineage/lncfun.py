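"""Guilt-by-association functional characterization of lncRNAs.

A lncRNA is *co-expressed* with a protein-coding gene when the absolute
Pearson correlation of their expression profiles exceeds 0.9. The GO terms
enriched (one-sided Fisher exact test, p < 0.01) in a lncRNA's co-expressed
gene group are attributed to the lncRNA itself. Enrichment can be run with
the classic per-term test or the topology-aware *elim* algorithm, which
tests terms children-before-parents and removes the genes of significant
child terms from their ancestors before those are tested.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError

COEXPR_THRESHOLD = 0.9
GO_ALPHA = 0.01
MIN_TERM_SIZE = 3

KNOWN_BIOTYPES = (
    "antisense",
    "lincRNA",
    "processed_transcript",
    "sense_intronic",
    "sense_overlapping",
    "3prime_overlapping_ncRNA",
)


def classify_biotype(lncrna_ids: Iterable[str], annotation: pd.DataFrame) -> pd.Series:
    """Tally lncRNAs per GENCODE-style biotype; unknown biotypes pool as 'other'."""
    ids = list(lncrna_ids)
    if not ids:
        return pd.Series(dtype=int)
    sub = annotation.set_index("gene_id").loc[ids]
    biotype = sub["biotype"].where(sub["biotype"].isin(KNOWN_BIOTYPES), "other")
    return biotype.value_counts().sort_index()


def coexpression_network(
    lnc_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    threshold: float = COEXPR_THRESHOLD,
) -> pd.DataFrame:
    """All (lncRNA, gene) pairs with |Pearson r| strictly above ``threshold``.

    Both matrices must share sample columns (>= 3). Constant-expression
    features have undefined correlation and contribute no edges (warned).
    """
    shared = [c for c in lnc_expr.columns if c in set(gene_expr.columns)]
    if len(shared) < 3:
        raise ValidationError("need >=3 shared samples for correlation")
    L = lnc_expr[shared].to_numpy(dtype=float)
    G = gene_expr[shared].to_numpy(dtype=float)
    n = len(shared)

    def standardize(M):
        sd = M.std(axis=1, ddof=0)
        const = sd == 0
        Z = (M - M.mean(axis=1, keepdims=True)) / np.where(const, 1.0, sd)[:, None]
        Z[const] = np.nan
        return Z, const

    ZL, const_l = standardize(L)
    ZG, const_g = standardize(G)
    if const_l.any() or const_g.any():
        warnings.warn(
            f"{int(const_l.sum())} lncRNAs and {int(const_g.sum())} genes have "
            "constant expression; excluded from the network",
            stacklevel=2,
        )
    R = ZL @ ZG.T / n
    li, gi = np.nonzero(np.abs(R) > threshold)
    edges = pd.DataFrame(
        {
            "lncrna_id": lnc_expr.index[li],
            "gene_id": gene_expr.index[gi],
            "r": R[li, gi],
            "n_samples": n,
        }
    )
    return edges.reset_index(drop=True)


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------

def validate_dag(dag: nx.DiGraph) -> str:
    """Check acyclicity and single-rootedness; return the root term."""
    if not nx.is_directed_acyclic_graph(dag):
        raise ValidationError("GO graph contains a cycle")
    roots = [t for t in dag.nodes if dag.out_degree(t) == 0]
    if len(roots) != 1:
        raise ValidationError(f"GO DAG must have exactly one root, found {len(roots)}")
    return roots[0]


def propagate_annotations(
    gene2terms: Mapping[str, set[str]], dag: nx.DiGraph
) -> dict[str, set[str]]:
    """True-path rule: term -> all genes annotated to it or any descendant."""
    validate_dag(dag)
    term_genes: dict[str, set[str]] = {t: set() for t in dag.nodes}
    for gene, terms in gene2terms.items():
        for term in terms:
            if term not in term_genes:
                continue
            term_genes[term].add(gene)
    # edges point child -> parent; accumulate in topological (children first) order
    for term in nx.topological_sort(dag):
        for parent in dag.successors(term):
            term_genes[parent] |= term_genes[term]
    return term_genes


def fisher_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """One-sided Fisher exact p = P(X >= k), X ~ Hypergeom(N, K, n)."""
    return float(scipy.stats.hypergeom.sf(k - 1, N, K, n))


def go_enrichment(
    study: set[str],
    universe: set[str],
    gene2terms: Mapping[str, set[str]],
    dag: nx.DiGraph,
    algorithm: str = "elim",
    alpha_elim: float = GO_ALPHA,
    min_term_size: int = MIN_TERM_SIZE,
) -> pd.DataFrame:
    """Per-term one-sided Fisher enrichment of ``study`` within ``universe``.

    ``algorithm='classic'`` tests each term on its full (propagated)
    annotation; ``'elim'`` walks the DAG children-before-parents and, whenever
    a term's p falls below ``alpha_elim``, removes its annotated genes from
    all its ancestors before those are tested. Terms annotating fewer than
    ``min_term_size`` universe genes are skipped.
    """
    if algorithm not in ("classic", "elim"):
        raise ValidationError(f"unknown GO algorithm {algorithm!r}")
    if not study <= universe:
        raise ValidationError("study set must be a subset of the universe")
    term_genes = propagate_annotations(gene2terms, dag)
    term_genes = {t: g & universe for t, g in term_genes.items()}
    N, n = len(universe), len(study)

    # children before parents; deterministic order within a topological level
    order = list(nx.lexicographical_topological_sort(dag))
    removed: dict[str, set[str]] = {t: set() for t in dag.nodes}
    rows = []
    for term in order:
        annotated = term_genes[term] - removed[term]
        K = len(annotated)
        if K < min_term_size:
            continue
        k = len(annotated & study)
        p = fisher_upper_tail(k, K, n, N)
        rows.append(
            {
                "term_id": term,
                "study_count": k,
                "study_size": n,
                "term_universe_count": K,
                "universe_size": N,
                "pvalue": p,
                "algorithm": algorithm,
            }
        )
        if algorithm == "elim" and p < alpha_elim:
            for anc in nx.descendants(dag, term):  # ancestors in GO sense
                removed[anc] |= annotated
    return pd.DataFrame(rows).sort_values(["pvalue", "term_id"]).reset_index(drop=True)


def attribute_terms_to_lncrnas(
    edges: pd.DataFrame,
    universe: set[str],
    gene2terms: Mapping[str, set[str]],
    dag: nx.DiGraph,
    algorithm: str = "elim",
    cutoff: float = GO_ALPHA,
    alpha_elim: float = GO_ALPHA,
) -> pd.DataFrame:
    """Run GO enrichment on each lncRNA's co-expressed gene group and
    attribute terms with p strictly below ``cutoff`` to the lncRNA."""
    rows = []
    for lncrna, sub in edges.groupby("lncrna_id"):
        study = set(sub["gene_id"]) & universe
        if not study:
            continue
        enr = go_enrichment(
            study, universe, gene2terms, dag, algorithm=algorithm, alpha_elim=alpha_elim
        )
        hits = enr[enr["pvalue"] < cutoff]
        for rec in hits.itertuples(index=False):
            rows.append(
                {
                    "lncrna_id": lncrna,
                    "term_id": rec.term_id,
                    "pvalue": rec.pvalue,
                    "algorithm": rec.algorithm,
                }
            )
    return pd.DataFrame(rows, columns=["lncrna_id", "term_id", "pvalue", "algorithm"])


def pair_correlation_trend(
    pairs: pd.DataFrame, lnc_expr: pd.DataFrame, gene_expr: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Pearson r for each (lncRNA, gene) vicinity pair, plus a summary
    (mean r, fraction positive) describing the expression trend."""
    if pairs.empty:
        return (
            pd.DataFrame(columns=["lncrna_id", "gene_id", "r"]),
            {"n_pairs": 0, "mean_r": float("nan"), "fraction_positive": float("nan")},
        )
    shared = [c for c in lnc_expr.columns if c in set(gene_expr.columns)]
    if len(shared) < 3:
        raise ValidationError("need >=3 shared samples for correlation")
    rs = []
    for lnc, gene in pairs[["lncrna_id", "gene_id"]].itertuples(index=False):
        x = lnc_expr.loc[lnc, shared].to_numpy(dtype=float)
        y = gene_expr.loc[gene, shared].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            rs.append(np.nan)
        else:
            rs.append(float(np.corrcoef(x, y)[0, 1]))
    out = pairs[["lncrna_id", "gene_id"]].copy()
    out["r"] = rs
    valid = out["r"].dropna()
    summary = {
        "n_pairs": int(len(out)),
        "mean_r": float(valid.mean()) if len(valid) else float("nan"),
        "fraction_positive": float((valid > 0).mean()) if len(valid) else float("nan"),
    }
    return out, summary
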