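"""Window arithmetic and mark-enrichment statistics around genomic features.

Enhancer marks are counted within +/-125 kb of a feature's transcription
start site, active-promoter marks within +/-2.5 kb. The enrichment of
lineage marks around a lineage-specific feature set is assessed by a
randomization test: the same number of features is drawn repeatedly from the
rest of the tested universe, the overlap recounted, and an empirical p-value
computed as (r + 1) / (n_iter + 1) where r is the number of null draws with
at least the observed count. The lncRNA vicinity rule pairs a lncRNA with a
gene when the lncRNA lies within 5 kb upstream or 30 kb downstream of the
gene body (strand-aware).

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ValidationError

ENHANCER_WINDOW = 125_000
PROMOTER_WINDOW = 2_500
VICINITY_UP = 5_000
VICINITY_DOWN = 30_000


@dataclass(frozen=True)
class WindowSpec:
    """How to build the interval around a feature."""

    upstream: int
    downstream: int
    anchor: str = "tss"  # "tss" | "body"
    strand_aware: bool = False

    def __post_init__(self):
        if self.upstream < 0 or self.downstream < 0:
            raise ValidationError("window extents must be non-negative")
        if self.anchor not in ("tss", "body"):
            raise ValidationError(f"unknown anchor {self.anchor!r}")


@dataclass
class EnrichmentResult:
    observed: int
    null_counts: np.ndarray = field(repr=False)
    empirical_p: float = 0.0
    n_iter: int = 0
    seed: int = 0

    def summary(self) -> dict:
        q = np.quantile(self.null_counts, [0.05, 0.5, 0.95]) if self.n_iter else [0, 0, 0]
        return {
            "observed": int(self.observed),
            "empirical_p": float(self.empirical_p),
            "n_iter": int(self.n_iter),
            "null_mean": float(np.mean(self.null_counts)) if self.n_iter else 0.0,
            "null_q05": float(q[0]),
            "null_median": float(q[1]),
            "null_q95": float(q[2]),
        }


def tss_of(features: pd.DataFrame) -> pd.Series:
    """TSS per feature: start on the + strand, end - 1 on the - strand.

    Unstranded features ('.') are treated as + strand.
    """
    minus = features["strand"] == "-"
    return pd.Series(
        np.where(minus, features["end"].to_numpy() - 1, features["start"].to_numpy()),
        index=features.index,
    )


def feature_window(feature, spec: WindowSpec) -> tuple[int, int]:
    """Interval around one feature (row of the annotation frame).

    TSS anchor: [tss - upstream, tss + downstream) oriented by strand when
    ``strand_aware``; the TSS base itself is always included, so a zero-width
    spec yields the single-bp TSS interval. Body anchor extends the gene body
    by upstream/downstream on the appropriate sides. Coordinates clamp at 0.
    """
    strand = getattr(feature, "strand", "+")
    if spec.strand_aware and strand not in ("+", "-"):
        if spec.upstream != spec.downstream:
            warnings.warn(
                "unstranded feature with asymmetric window: treating as + strand",
                stacklevel=2,
            )
        strand = "+"
    flip = spec.strand_aware and strand == "-"
    up, down = (spec.downstream, spec.upstream) if flip else (spec.upstream, spec.downstream)
    if spec.anchor == "tss":
        t = int(feature.end) - 1 if strand == "-" else int(feature.start)
        start, end = t - up, max(t + down, t + 1)
    else:
        start, end = int(feature.start) - up, int(feature.end) + down
    return max(start, 0), end


def feature_windows(features: pd.DataFrame, spec: WindowSpec) -> pd.DataFrame:
    """Vectorized :func:`feature_window` over an annotation frame."""
    strand = features["strand"].where(features["strand"].isin(["+", "-"]), "+")
    flip = spec.strand_aware & (strand == "-").to_numpy()
    up = np.where(flip, spec.downstream, spec.upstream)
    down = np.where(flip, spec.upstream, spec.downstream)
    if spec.anchor == "tss":
        t = np.where(
            strand.to_numpy() == "-",
            features["end"].to_numpy() - 1,
            features["start"].to_numpy(),
        )
        start, end = t - up, np.maximum(t + down, t + 1)
    else:
        start = features["start"].to_numpy() - up
        end = features["end"].to_numpy() + down
    return pd.DataFrame(
        {
            "chrom": features["chrom"].to_numpy(),
            "start": np.maximum(start, 0),
            "end": end,
        },
        index=features.index,
    )


def _mark_trees(marks: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in marks.groupby("chrom"):
        tree = IntervalTree()
        for idx, s, e in zip(sub.index, sub["start"], sub["end"]):
            tree.addi(int(s), int(e), idx)
        trees[str(chrom)] = tree
    return trees


def mark_overlap_sets(
    features: pd.DataFrame, marks: pd.DataFrame, spec: WindowSpec
) -> list[np.ndarray]:
    """Per feature, the indices of mark intervals overlapping its window."""
    windows = feature_windows(features, spec)
    trees = _mark_trees(marks)
    out: list[np.ndarray] = []
    for chrom, start, end in windows.itertuples(index=False):
        tree = trees.get(str(chrom))
        if tree is None:
            out.append(np.empty(0, dtype=np.int64))
            continue
        hits = tree.overlap(int(start), int(end))
        out.append(np.fromiter((h.data for h in hits), dtype=np.int64, count=len(hits)))
    return out


def count_marks_near_set(
    features: pd.DataFrame,
    marks: pd.DataFrame,
    spec: WindowSpec,
    dedup: bool = True,
) -> int:
    """Number of mark intervals overlapping the union of feature windows.

    With ``dedup`` (default) a mark near two features counts once; otherwise
    each feature window counts its overlapping marks separately.
    """
    if len(features) == 0:
        return 0
    sets = mark_overlap_sets(features, marks, spec)
    if dedup:
        return int(np.unique(np.concatenate(sets)).size) if sets else 0
    return int(sum(len(s) for s in sets))


def randomization_enrichment(
    target: pd.DataFrame,
    universe: pd.DataFrame,
    marks: pd.DataFrame,
    spec: WindowSpec,
    n_iter: int = 10_000,
    seed: int = 0,
    exclude_target: bool = True,
    dedup: bool = True,
) -> EnrichmentResult:
    """Empirical enrichment of marks near ``target`` vs random same-size sets.

    Null sets are drawn uniformly without replacement from the universe
    (excluding the target itself by default, i.e. "anywhere else"), the mark
    overlap is recounted for each draw, and the empirical p-value is
    (#{null >= observed} + 1) / (n_iter + 1) — never exactly zero.
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    if not set(target.index).issubset(set(universe.index)):
        raise ValidationError("target features must be a subset of the universe")
    sets = mark_overlap_sets(universe, marks, spec)
    pos = {fid: i for i, fid in enumerate(universe.index)}
    target_pos = np.array([pos[f] for f in target.index], dtype=np.int64)
    observed = _union_count(sets, target_pos, dedup)

    if exclude_target:
        pool = np.setdiff1d(np.arange(len(universe)), target_pos)
    else:
        pool = np.arange(len(universe))
    k = len(target_pos)
    if len(pool) < k:
        raise ValidationError(
            f"sampling pool ({len(pool)}) smaller than target set ({k})"
        )
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter, dtype=np.int64)
    for i in range(n_iter):
        draw = rng.choice(pool, size=k, replace=False)
        null[i] = _union_count(sets, draw, dedup)
    r = int(np.count_nonzero(null >= observed))
    return EnrichmentResult(
        observed=int(observed),
        null_counts=null,
        empirical_p=(r + 1) / (n_iter + 1),
        n_iter=n_iter,
        seed=seed,
    )


def _union_count(sets: list[np.ndarray], idx: np.ndarray, dedup: bool) -> int:
    picked = [sets[i] for i in idx]
    if not picked:
        return 0
    if dedup:
        return int(np.unique(np.concatenate(picked)).size)
    return int(sum(len(s) for s in picked))


def lncrna_gene_vicinity(
    lncrnas: pd.DataFrame,
    genes: pd.DataFrame,
    upstream: int = VICINITY_UP,
    downstream: int = VICINITY_DOWN,
    anchor: str = "body",
    strand_aware: bool = True,
) -> pd.DataFrame:
    """(lncRNA, gene) pairs where the lncRNA body overlaps the gene's
    vicinity window (default: 5 kb upstream to 30 kb downstream of the gene
    body, oriented by gene strand). A lncRNA may pair with several genes.
    """
    spec = WindowSpec(upstream, downstream, anchor=anchor, strand_aware=strand_aware)
    pairs: list[tuple[str, str]] = []
    if len(lncrnas) and len(genes):
        lnc_trees: dict[str, IntervalTree] = {}
        for chrom, sub in lncrnas.groupby("chrom"):
            tree = IntervalTree()
            for gid, s, e in zip(sub["gene_id"], sub["start"], sub["end"]):
                tree.addi(int(s), int(e), gid)
            lnc_trees[str(chrom)] = tree
        windows = feature_windows(genes, spec)
        for (chrom, ws, we), gid in zip(
            windows.itertuples(index=False), genes["gene_id"]
        ):
            tree = lnc_trees.get(str(chrom))
            if tree is None:
                continue
            for hit in tree.overlap(int(ws), int(we)):
                pairs.append((hit.data, gid))
    out = pd.DataFrame(sorted(set(pairs)), columns=["lncrna_id", "gene_id"])
    return out
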