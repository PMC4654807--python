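"""Disease-associated SNP filtering and trait enrichment.

SNPs with association p > 1e-5 are excluded; a gene is associated with a
SNP's trait when it lies within +/-100 kb of the SNP position (distance to
the gene body, strand-independent). Trait enrichment in a lineage-specific
feature set is the upper tail of the hypergeometric distribution: drawing
n = |lineage set| genes from a universe of N, of which K are associated with
the trait, what is the probability of >= k overlaps?
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError

SNP_P_THRESHOLD = 1e-5
SNP_WINDOW = 100_000


def filter_snps(snps: pd.DataFrame, threshold: float = SNP_P_THRESHOLD) -> pd.DataFrame:
    """Retain SNPs with association p <= threshold (p > threshold excluded)."""
    if snps.empty:
        return snps.copy()
    return snps[snps["pvalue"] <= threshold].reset_index(drop=True)


def associate_genes(
    snps: pd.DataFrame, genes: pd.DataFrame, window: int = SNP_WINDOW
) -> dict[str, set[str]]:
    """gene_id -> set of traits with a SNP within ``window`` bp of the gene body.

    Distance is 0 for a SNP inside the body [start, end); otherwise the gap to
    the nearest body base. A gene hit by several SNPs of one trait counts once.
    """
    out: dict[str, set[str]] = {}
    if snps.empty or genes.empty:
        return out
    for chrom, gsub in genes.groupby("chrom"):
        ssub = snps[snps["chrom"] == chrom]
        if ssub.empty:
            continue
        pos = ssub["pos"].to_numpy(dtype=np.int64)
        traits = ssub["trait"].to_numpy()
        starts = gsub["start"].to_numpy(dtype=np.int64)
        ends = gsub["end"].to_numpy(dtype=np.int64)
        for gid, s, e in zip(gsub["gene_id"], starts, ends):
            dist = np.maximum.reduce([s - pos, pos - (e - 1), np.zeros_like(pos)])
            hit = dist <= window
            if hit.any():
                out.setdefault(gid, set()).update(traits[hit])
    return out


def trait_hypergeometric_test(
    lineage_set: set[str],
    trait_assoc: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each trait in ``lineage_set``.

    Returns one row per trait with k (overlap), n (lineage set size),
    K (trait-associated genes in the universe), N (universe size) and the
    p-value, sorted by p.
    """
    if not universe:
        raise ValidationError("empty universe")
    if not lineage_set <= universe:
        raise ValidationError("lineage set must be a subset of the universe")
    trait_genes: dict[str, set[str]] = {}
    for gene, traits in trait_assoc.items():
        if gene not in universe:
            continue
        for trait in traits:
            trait_genes.setdefault(trait, set()).add(gene)
    N, n = len(universe), len(lineage_set)
    rows = []
    for trait in sorted(trait_genes):
        K = len(trait_genes[trait])
        k = len(trait_genes[trait] & lineage_set)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"trait": trait, "k": k, "n": n, "K": K, "N": N, "pvalue": p})
    out = pd.DataFrame(rows, columns=["trait", "k", "n", "K", "N", "pvalue"])
    return out.sort_values(["pvalue", "trait"]).reset_index(drop=True)
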