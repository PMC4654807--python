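"""Synthetic multi-platform T-helper differentiation datasets with planted truth.

The generator emulates the study design the pipeline is built for: naive
precursor (Thp), activated (Th0) and polarized (Th1, Th2) CD4+ T cells at an
early differentiation time point, profiled in replicate on two array-like
intensity platforms and one sequencing count platform. Expression is bimodal
on the log2 scale (an unexpressed low-mean component and an expressed
high-mean component); lineage-specific genes and lncRNAs are planted by
shifting their polarized-group signal by +/- ``effect_lfc`` with a sign that
is consistent across platforms and applied *only* in the matching polarized
group — never in Th0 — so the lineage-specificity definition is exercised
exactly. Around planted genes the matching lineage's enhancer/promoter mark
density is multiplied by ``mark_enrichment_factor``; selected traits get
genome-wide-significant SNPs clustered within +/-100 kb of planted genes; a
small GO DAG annotates one term with planted co-regulated genes so
guilt-by-association can recover it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io
from .containers import GROUPS, ExpressionMatrix, GroundTruth
from .errors import PlacementError, ValidationError

LNCRNA_BIOTYPES = (
    ("antisense", 0.48),
    ("lincRNA", 0.26),
    ("processed_transcript", 0.19),
    ("sense_intronic", 0.05),
    ("sense_overlapping", 0.012),
    ("3prime_overlapping_ncRNA", 0.008),
)

BACKGROUND_TRAITS = (
    "height",
    "body mass index",
    "type 2 diabetes",
    "coronary artery disease",
    "bone mineral density",
    "age-related macular degeneration",
    "schizophrenia",
    "blood pressure",
    "LDL cholesterol",
    "platelet count",
)


@dataclass
class SyntheticConfig:
    """Generating conditions for a synthetic dataset (defaults = demo scale)."""

    n_genes: int = 10_000
    n_lncrnas: int = 200
    n_th1_genes: int = 300
    n_th2_genes: int = 300
    n_th1_lncrnas: int = 30
    n_th2_lncrnas: int = 30
    effect_lfc: float = 2.0
    replicates_per_group: int = 3
    platforms: tuple[tuple[str, str], ...] = (
        ("affy", "intensity"),
        ("illumina", "intensity"),
        ("rnaseq", "count"),
    )
    expressed_fraction: float = 0.7
    mixture_means: tuple[float, float] = (4.0, 9.0)  # log2 scale, (low, high)
    mixture_sds: tuple[float, float] = (1.0, 1.0)
    replicate_sd: float = 0.25  # within-group technical noise, log2 scale
    nb_dispersion: float = 0.05  # negative-binomial dispersion, count platform
    depth_sd: float = 0.3  # log-normal library-depth spread, count platform
    genome_length: int = 250_000_000
    n_chromosomes: int = 1
    gene_length_range: tuple[int, int] = (1_000, 10_000)
    lncrna_length_range: tuple[int, int] = (500, 5_000)
    vicinity_fraction: float = 0.5  # planted lineage lncRNAs placed near lineage genes
    mark_enrichment_factor: float = 5.0
    n_background_marks: int = 3_000  # per lineage, per mark class
    enhancer_length: int = 1_000
    promoter_length: int = 500
    snp_cluster_traits: tuple[str, ...] = ("celiac disease",)
    n_background_snps: int = 2_000
    n_cluster_snps: int = 30
    snp_significant_fraction: float = 0.5
    go_levels: tuple[int, int, int] = (5, 12, 25)
    go_term_size_range: tuple[int, int] = (10, 30)
    planted_go_term_size: int = 25
    seed: int = 0

    def validate(self) -> None:
        counts = [
            self.n_genes,
            self.n_lncrnas + 1,
            self.replicates_per_group,
            self.genome_length,
        ]
        if any(c <= 0 for c in counts):
            raise ValidationError("all counts must be positive")
        if self.n_th1_genes + self.n_th2_genes > self.n_genes:
            raise ValidationError("planted gene sets exceed n_genes")
        if self.n_th1_lncrnas + self.n_th2_lncrnas > self.n_lncrnas:
            raise ValidationError("planted lncRNA sets exceed n_lncrnas")
        if not (0 < self.expressed_fraction < 1):
            raise ValidationError("expressed_fraction must lie in (0, 1)")
        if self.effect_lfc < 0:
            raise ValidationError("effect_lfc must be non-negative")
        if self.mixture_means[0] >= self.mixture_means[1]:
            raise ValidationError("mixture means must be ordered low < high")
        if len(self.platforms) < 1:
            raise ValidationError("need at least one platform")


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, plus the planted ground truth."""

    config: SyntheticConfig
    annotation: pd.DataFrame
    matrices: list[ExpressionMatrix]
    detection_p: dict[str, pd.DataFrame]
    enhancers: pd.DataFrame
    promoters: pd.DataFrame
    snps: pd.DataFrame
    go_dag: nx.DiGraph
    gene2terms: dict[str, set[str]]
    truth: GroundTruth

    @property
    def genes(self) -> pd.DataFrame:
        return self.annotation[self.annotation["biotype"] == "protein_coding"]

    @property
    def lncrnas(self) -> pd.DataFrame:
        return self.annotation[self.annotation["biotype"] != "protein_coding"]


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full dataset; deterministic for a given config (incl. seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    annotation, truth = generate_annotation(config, rng)
    matrices, detection_p = generate_expression(config, annotation, truth, rng)
    enhancers, promoters = generate_marks(config, annotation, truth, rng)
    snps = generate_snps(config, annotation, truth, rng)
    go_dag, gene2terms = generate_go(config, annotation, truth, rng)
    return SyntheticDataset(
        config=config,
        annotation=annotation,
        matrices=matrices,
        detection_p=detection_p,
        enhancers=enhancers,
        promoters=promoters,
        snps=snps,
        go_dag=go_dag,
        gene2terms=gene2terms,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, GroundTruth]:
    """Place non-overlapping genes and lncRNAs on synthetic chromosome(s).

    A configured fraction of each lineage's planted lncRNAs is placed inside
    the 5 kb-upstream / 30 kb-downstream vicinity window of a planted gene of
    the same lineage (strand-aware by gene strand); the rest, and all
    background lncRNAs, land uniformly in unoccupied space.
    """
    config.validate()
    n_g, n_l = config.n_genes, config.n_lncrnas
    gene_len = rng.integers(*config.gene_length_range, size=n_g, endpoint=True)
    lnc_len = rng.integers(*config.lncrna_length_range, size=n_l, endpoint=True)
    needed = int(gene_len.sum() + lnc_len.sum())
    if needed * 1.5 > config.genome_length:
        raise PlacementError(
            f"genome_length {config.genome_length} too small for ~{needed} bp of features"
        )

    # genes first: random gaps spanning the whole genome
    slack = config.genome_length - int(gene_len.sum())
    frac = rng.random(n_g + 1)
    gaps = np.floor(frac / frac.sum() * slack).astype(np.int64)
    starts = np.empty(n_g, dtype=np.int64)
    cursor = 0
    for i in range(n_g):
        cursor += gaps[i]
        starts[i] = cursor
        cursor += gene_len[i]
    ends = starts + gene_len
    gene_ids = np.array([f"G{i:05d}" for i in range(n_g)])
    gene_strand = rng.choice(["+", "-"], size=n_g)

    # planted lineage genes
    planted = rng.choice(n_g, size=config.n_th1_genes + config.n_th2_genes, replace=False)
    th1_gene_idx = planted[: config.n_th1_genes]
    th2_gene_idx = planted[config.n_th1_genes :]
    truth = GroundTruth(
        th1_genes=set(gene_ids[th1_gene_idx]), th2_genes=set(gene_ids[th2_gene_idx])
    )

    chrom = _chrom_of(starts, config)
    occupied_starts = starts.copy()
    occupied_ends = ends.copy()

    # lncRNAs: lineage assignment, then placement
    lnc_ids = np.array([f"L{i:04d}" for i in range(n_l)])
    lnc_assign = rng.permutation(n_l)
    th1_lnc_idx = lnc_assign[: config.n_th1_lncrnas]
    th2_lnc_idx = lnc_assign[config.n_th1_lncrnas : config.n_th1_lncrnas + config.n_th2_lncrnas]
    truth.th1_lncrnas = set(lnc_ids[th1_lnc_idx])
    truth.th2_lncrnas = set(lnc_ids[th2_lnc_idx])

    lnc_start = np.empty(n_l, dtype=np.int64)
    lnc_strand = rng.choice(["+", "-"], size=n_l)

    def place_free(length: int) -> int:
        for _ in range(1000):
            s = int(rng.integers(0, config.genome_length - length))
            if _is_free(occupied_starts, occupied_ends, s, s + length):
                return s
        raise PlacementError("could not place a feature in free space")

    def place_in_vicinity(length: int, gidx: int) -> int | None:
        """Place within [start-5kb, end+30kb) of the gene, strand-oriented."""
        gs, ge = int(starts[gidx]), int(ends[gidx])
        if gene_strand[gidx] == "+":
            lo, hi = gs - 5_000, ge + 30_000
        else:
            lo, hi = gs - 30_000, ge + 5_000
        lo = max(lo, 0)
        hi = min(hi, config.genome_length)
        if hi - lo <= length:
            return None
        for _ in range(200):
            s = int(rng.integers(lo, hi - length))
            if _is_free(occupied_starts, occupied_ends, s, s + length):
                return s
        return None

    vicinity_target: dict[int, int] = {}  # lnc index -> gene index
    for lineage_lnc, lineage_gene_idx in (
        (th1_lnc_idx, th1_gene_idx),
        (th2_lnc_idx, th2_gene_idx),
    ):
        n_vic = int(round(config.vicinity_fraction * len(lineage_lnc)))
        candidates = list(rng.permutation(lineage_gene_idx))
        for li in lineage_lnc[:n_vic]:
            while candidates:
                gidx = candidates.pop()
                s = place_in_vicinity(int(lnc_len[li]), int(gidx))
                if s is not None:
                    vicinity_target[int(li)] = int(gidx)
                    lnc_start[li] = s
                    occupied_starts, occupied_ends = _occupy(
                        occupied_starts, occupied_ends, s, s + int(lnc_len[li])
                    )
                    break

    for li in range(n_l):
        if li in vicinity_target:
            continue
        s = place_free(int(lnc_len[li]))
        lnc_start[li] = s
        occupied_starts, occupied_ends = _occupy(
            occupied_starts, occupied_ends, s, s + int(lnc_len[li])
        )

    truth.vicinity_pairs = {
        (str(lnc_ids[li]), str(gene_ids[gi])) for li, gi in vicinity_target.items()
    }

    probs = np.array([p for _, p in LNCRNA_BIOTYPES])
    biotypes = rng.choice(
        [b for b, _ in LNCRNA_BIOTYPES], size=n_l, p=probs / probs.sum()
    )
    annotation = pd.concat(
        [
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "gene_name": gene_ids,
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "strand": gene_strand,
                    "biotype": "protein_coding",
                }
            ),
            pd.DataFrame(
                {
                    "gene_id": lnc_ids,
                    "gene_name": lnc_ids,
                    "chrom": _chrom_of(lnc_start, config),
                    "start": lnc_start,
                    "end": lnc_start + lnc_len,
                    "strand": lnc_strand,
                    "biotype": biotypes,
                }
            ),
        ],
        ignore_index=True,
    )
    annotation = annotation.sort_values(["chrom", "start"]).reset_index(drop=True)
    return annotation, truth


def _chrom_of(positions: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Map linear coordinates onto equal-sized synthetic chromosomes."""
    if config.n_chromosomes <= 1:
        return np.full(len(positions), "chr1")
    size = config.genome_length // config.n_chromosomes
    idx = np.minimum(positions // size, config.n_chromosomes - 1)
    return np.array([f"chr{i + 1}" for i in idx])


def _is_free(starts: np.ndarray, ends: np.ndarray, s: int, e: int) -> bool:
    i = np.searchsorted(starts, s)
    if i < len(starts) and starts[i] < e:
        return False
    if i > 0 and ends[i - 1] > s:
        return False
    return True


def _occupy(starts, ends, s, e):
    i = np.searchsorted(starts, s)
    return np.insert(starts, i, s), np.insert(ends, i, e)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(
    config: SyntheticConfig,
    annotation: pd.DataFrame,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[list[ExpressionMatrix], dict[str, pd.DataFrame]]:
    """One matrix per platform over shared feature ids, plus detection
    p-values for Illumina-style intensity platforms."""
    feature_ids = annotation["gene_id"].to_numpy()
    n_feat = len(feature_ids)
    expressed = rng.random(n_feat) < config.expressed_fraction
    planted_all = truth.th1_genes | truth.th2_genes | truth.th1_lncrnas | truth.th2_lncrnas
    planted_mask = np.isin(feature_ids, sorted(planted_all))
    expressed |= planted_mask  # planted features must be detectable

    signs = rng.choice([1, -1], size=n_feat)
    # a lncRNA planted in a gene's vicinity is co-regulated with it in cis:
    # it inherits the gene's effect sign (the observed positive pair trend)
    sign_of = dict(zip(feature_ids, signs))
    for lnc, gene in truth.vicinity_pairs:
        sign_of[lnc] = sign_of[gene]
    signs = np.array([sign_of[f] for f in feature_ids])
    effect = np.zeros(n_feat)
    lineage_of = np.full(n_feat, "", dtype=object)
    th1_mask = np.isin(feature_ids, sorted(truth.th1_genes | truth.th1_lncrnas))
    th2_mask = np.isin(feature_ids, sorted(truth.th2_genes | truth.th2_lncrnas))
    if config.effect_lfc > 0:
        effect[th1_mask | th2_mask] = config.effect_lfc * signs[th1_mask | th2_mask]
        lineage_of[th1_mask] = "Th1"
        lineage_of[th2_mask] = "Th2"
        truth.effect_signs = {
            str(f): int(s)
            for f, s, m in zip(feature_ids, signs, th1_mask | th2_mask)
            if m
        }
    else:
        truth.th1_genes = set()
        truth.th2_genes = set()
        truth.th1_lncrnas = set()
        truth.th2_lncrnas = set()
        truth.vicinity_pairs = set()

    samples = [f"{g}_r{r + 1}" for g in GROUPS for r in range(config.replicates_per_group)]
    sample_groups = np.array([s.split("_")[0] for s in samples])
    design = pd.DataFrame(
        {
            "sample": samples,
            "group": sample_groups,
            "replicate": [int(s.split("_r")[1]) for s in samples],
        }
    )
    truth.expressed_features = {
        g: set(feature_ids[expressed]) for g in GROUPS
    }

    mu_low, mu_high = config.mixture_means
    sd_low, sd_high = config.mixture_sds
    matrices: list[ExpressionMatrix] = []
    detection: dict[str, pd.DataFrame] = {}
    for name, kind in config.platforms:
        baseline = np.where(
            expressed,
            rng.normal(mu_high, sd_high, size=n_feat),
            rng.normal(mu_low, sd_low, size=n_feat),
        )
        signal = np.tile(baseline[:, None], (1, len(samples)))
        for j, group in enumerate(sample_groups):
            hit = lineage_of == group
            signal[hit, j] += effect[hit]
        if kind == "intensity":
            values = signal + rng.normal(0, config.replicate_sd, size=signal.shape)
            df = pd.DataFrame(values, index=feature_ids, columns=samples)
            matrices.append(
                ExpressionMatrix(values=df, design=design, platform_kind="intensity", platform=name)
            )
            if "illumina" in name:
                det = np.where(
                    expressed[:, None],
                    rng.uniform(0, 0.005, size=signal.shape),
                    rng.uniform(0, 1, size=signal.shape),
                )
                detection[name] = pd.DataFrame(det, index=feature_ids, columns=samples)
        else:
            depth = rng.lognormal(0.0, config.depth_sd, size=len(samples))
            mu = np.exp2(signal) * depth[None, :]
            if config.nb_dispersion > 0:
                r = 1.0 / config.nb_dispersion
                counts = rng.negative_binomial(r, r / (r + mu))
            else:
                counts = rng.poisson(mu)
            df = pd.DataFrame(counts.astype(np.int64), index=feature_ids, columns=samples)
            matrices.append(
                ExpressionMatrix(values=df, design=design, platform_kind="count", platform=name)
            )
    return matrices, detection


# ---------------------------------------------------------------------------
# epigenetic marks
# ---------------------------------------------------------------------------

def generate_marks(
    config: SyntheticConfig,
    annotation: pd.DataFrame,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lineage-labelled enhancer and promoter intervals.

    Background marks are uniform over the genome; inside the TSS windows of
    planted genes of the matching lineage, density is multiplied by
    ``mark_enrichment_factor`` (extra marks drawn Poisson on top of the
    uniform expectation).
    """
    genes = annotation[annotation["biotype"] == "protein_coding"].set_index("gene_id")
    out = {}
    for mark_class, window, length in (
        ("enhancer", 125_000, config.enhancer_length),
        ("promoter", 2_500, config.promoter_length),
    ):
        rows = []
        density = config.n_background_marks / config.genome_length
        for lineage, planted_ids in (("Th1", truth.th1_genes), ("Th2", truth.th2_genes)):
            starts = rng.integers(
                0, config.genome_length - length, size=config.n_background_marks
            )
            for s in starts:
                rows.append((int(s), int(s) + length, lineage))
            extra_rate = (config.mark_enrichment_factor - 1.0) * density
            for gid in sorted(planted_ids):
                g = genes.loc[gid]
                tss = int(g["end"]) - 1 if g["strand"] == "-" else int(g["start"])
                lo = max(tss - window, 0)
                hi = min(tss + window, config.genome_length - length)
                if hi <= lo:
                    continue
                n_extra = rng.poisson(extra_rate * (hi - lo))
                for s in rng.integers(lo, hi, size=n_extra):
                    rows.append((int(s), int(s) + length, lineage))
                if extra_rate > 0:
                    truth.enriched_mark_regions.append(
                        ("chr1", lo, hi, lineage, mark_class)
                    )
        df = pd.DataFrame(rows, columns=["start", "end", "name"])
        df.insert(0, "chrom", _chrom_of(df["start"].to_numpy(), config))
        out[mark_class] = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return out["enhancer"], out["promoter"]


# ---------------------------------------------------------------------------
# SNPs
# ---------------------------------------------------------------------------

def generate_snps(
    config: SyntheticConfig,
    annotation: pd.DataFrame,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Background SNPs uniform over the genome with association p-values
    spanning both sides of 1e-5; for each configured cluster trait,
    genome-wide-significant SNPs placed within +/-100 kb of planted genes of
    one lineage (alternating Th1/Th2 across traits)."""
    rows = []
    n_bg = config.n_background_snps
    pos = rng.integers(0, config.genome_length, size=n_bg)
    traits = rng.choice(BACKGROUND_TRAITS, size=n_bg)
    sig = rng.random(n_bg) < config.snp_significant_fraction
    pvals = np.where(
        sig,
        10.0 ** -rng.uniform(5, 12, size=n_bg),
        10.0 ** -rng.uniform(0, 5, size=n_bg),
    )
    for p_, t_, pv in zip(pos, traits, pvals):
        rows.append((int(p_), str(t_), float(pv)))

    genes = annotation[annotation["biotype"] == "protein_coding"].set_index("gene_id")
    for i, trait in enumerate(config.snp_cluster_traits):
        lineage_genes = sorted(truth.th1_genes if i % 2 == 0 else truth.th2_genes)
        if not lineage_genes:
            continue
        chosen = rng.choice(
            lineage_genes, size=min(config.n_cluster_snps, len(lineage_genes)), replace=False
        )
        truth.trait_gene_map[trait] = set(map(str, chosen))
        for gid in chosen:
            g = genes.loc[gid]
            lo = max(int(g["start"]) - 100_000, 0)
            hi = min(int(g["end"]) - 1 + 100_000, config.genome_length - 1)
            s = int(rng.integers(lo, hi + 1))
            rows.append((s, trait, float(10.0 ** -rng.uniform(5, 12))))

    snps = pd.DataFrame(rows, columns=["pos", "trait", "pvalue"])
    snps.insert(0, "chrom", _chrom_of(snps["pos"].to_numpy(), config))
    return snps.sort_values(["chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene ontology
# ---------------------------------------------------------------------------

def generate_go(
    config: SyntheticConfig,
    annotation: pd.DataFrame,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[nx.DiGraph, dict[str, set[str]]]:
    """A small rooted is_a DAG plus direct gene annotations.

    One leaf term is "planted": its annotated genes are drawn from the Th1
    lineage genes, which share the polarized expression pattern and are
    therefore co-expressed with the planted Th1 lncRNA.
    """
    n1, n2, n3 = config.go_levels
    root = "GO:0000001"
    dag = nx.DiGraph()
    dag.add_node(root)
    lvl1 = [f"GO:10{i:05d}" for i in range(n1)]
    lvl2 = [f"GO:20{i:05d}" for i in range(n2)]
    lvl3 = [f"GO:30{i:05d}" for i in range(n3)]
    for t in lvl1:
        dag.add_edge(t, root)
    for t in lvl2:
        parents = rng.choice(lvl1, size=int(rng.integers(1, 3)), replace=False)
        for p in parents:
            dag.add_edge(t, p)
    for t in lvl3:
        parents = rng.choice(lvl2, size=int(rng.integers(1, 3)), replace=False)
        for p in parents:
            dag.add_edge(t, p)

    genes = annotation.loc[annotation["biotype"] == "protein_coding", "gene_id"].tolist()
    gene2terms: dict[str, set[str]] = {}

    def annotate(term: str, members) -> None:
        for g in members:
            gene2terms.setdefault(str(g), set()).add(term)

    lo, hi = config.go_term_size_range
    for term in lvl2 + lvl3:
        size = int(rng.integers(lo, hi + 1))
        annotate(term, rng.choice(genes, size=min(size, len(genes)), replace=False))

    th1 = sorted(truth.th1_genes)
    if th1 and truth.th1_lncrnas:
        planted_term = lvl3[0]
        members = rng.choice(
            th1, size=min(config.planted_go_term_size, len(th1)), replace=False
        )
        # replace the term's random annotation with the planted module
        for g in list(gene2terms):
            gene2terms[g].discard(planted_term)
            if not gene2terms[g]:
                del gene2terms[g]
        annotate(planted_term, members)
        truth.planted_go_term = planted_term
        truth.planted_go_lncrna = sorted(truth.th1_lncrnas)[0]
    return dag, gene2terms


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_dataset(data: SyntheticDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sheets = []
    for m in data.matrices:
        io.write_expression(m.values, out / f"expr_{m.platform}.tsv")
        sheet = m.design.copy()
        sheet["platform"] = m.platform
        sheet["platform_kind"] = m.platform_kind
        sheets.append(sheet)
    io.write_sample_sheet(pd.concat(sheets, ignore_index=True), out / "samples.tsv")
    for name, det in data.detection_p.items():
        io.write_expression(det, out / f"detection_{name}.tsv")
    io.write_gtf(data.annotation, out / "annotation.gtf")
    io.write_bed(data.enhancers, out / "enhancers.bed")
    io.write_bed(data.promoters, out / "promoters.bed")
    io.write_snps(data.snps, out / "snps.tsv")
    io.write_go_edges(data.go_dag, out / "go_edges.tsv")
    io.write_gene2term(data.gene2terms, out / "gene2term.tsv")
    io.write_json(data.truth.to_dict(), out / "truth.json")


def load_dataset(data_dir: str | Path) -> SyntheticDataset:
    """Re-load a written dataset (config is not round-tripped)."""
    d = Path(data_dir)
    sheet = io.read_sample_sheet(d / "samples.tsv")
    matrices = []
    detection = {}
    for platform, sub in sheet.groupby("platform", sort=False):
        kind = sub["platform_kind"].iloc[0]
        values = io.read_expression(d / f"expr_{platform}.tsv")
        design = sub[["sample", "group", "replicate"]].reset_index(drop=True)
        matrices.append(
            ExpressionMatrix(values=values, design=design, platform_kind=kind, platform=platform)
        )
        det_path = d / f"detection_{platform}.tsv"
        if det_path.exists():
            detection[platform] = io.read_expression(det_path)
    return SyntheticDataset(
        config=SyntheticConfig(),
        annotation=io.read_gtf(d / "annotation.gtf"),
        matrices=matrices,
        detection_p=detection,
        enhancers=io.read_bed(d / "enhancers.bed")[["chrom", "start", "end", "name"]],
        promoters=io.read_bed(d / "promoters.bed")[["chrom", "start", "end", "name"]],
        snps=io.read_snps(d / "snps.tsv"),
        go_dag=io.read_go_edges(d / "go_edges.tsv"),
        gene2terms=io.read_gene2term(d / "gene2term.tsv"),
        truth=GroundTruth.from_dict(io.read_json(d / "truth.json")),
    )
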