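"""Readers and writers for the plain-text formats used by the pipeline.

All genomic coordinates are held 0-based half-open in memory. GTF files are
read/written 1-based inclusive (the conversion happens at the boundary); BED
is native 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import ValidationError

ANNOTATION_COLUMNS = ["gene_id", "gene_name", "chrom", "start", "end", "strand", "biotype"]


# ---------------------------------------------------------------------------
# expression matrices and sample sheets
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a features x samples TSV (first column = feature_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet: columns sample, group, replicate, platform."""
    sheet = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str})
    required = {"sample", "group", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotation (GTF)
# ---------------------------------------------------------------------------

def write_gtf(annotation: pd.DataFrame, path: str | Path, source: str = "thlineage") -> None:
    """Write gene records as GTF (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for row in annotation.itertuples(index=False):
            attrs = (
                f'gene_id "{row.gene_id}"; gene_name "{row.gene_name}"; '
                f'gene_type "{row.biotype}";'
            )
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


def read_gtf(path: str | Path) -> pd.DataFrame:
    """Read gene records from a GTF into the internal annotation frame.

    Uses pyranges for the parse; coordinates come back 0-based half-open.
    """
    import pyranges  # deferred: slow import

    df = pyranges.read_gtf(str(path)).df
    df = df[df["Feature"] == "gene"]
    if "gene_name" not in df.columns:
        df["gene_name"] = df["gene_id"]
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"].astype(str),
            "gene_name": df["gene_name"].astype(str),
            "chrom": df["Chromosome"].astype(str),
            "start": df["Start"].astype(int),
            "end": df["End"].astype(int),
            "strand": df["Strand"].astype(str),
            "biotype": df["gene_type"].astype(str),
        }
    )
    # canonical coordinate order (pyranges groups rows by strand internally)
    return out.sort_values(["chrom", "start", "gene_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# intervals (BED6)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """BED6: chrom, start, end, name (lineage label), score, strand."""
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=[0, 1, 2, 3, 4, 5],
        dtype={0: str, 3: str},
    )
    if (bed["start"] >= bed["end"]).any():
        raise ValidationError("BED intervals must satisfy start < end")
    return bed


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    out = intervals.copy()
    if "score" not in out.columns:
        out["score"] = 0
    if "strand" not in out.columns:
        out["strand"] = "."
    out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# SNPs
# ---------------------------------------------------------------------------

def read_snps(path: str | Path) -> pd.DataFrame:
    snps = pd.read_csv(path, sep="\t", dtype={"chrom": str, "trait": str})
    required = {"chrom", "pos", "trait", "pvalue"}
    missing = required - set(snps.columns)
    if missing:
        raise ValidationError(f"SNP table missing columns: {sorted(missing)}")
    bad = (snps["pvalue"] <= 0) | (snps["pvalue"] > 1)
    if bad.any():
        raise ValidationError("SNP association p-values must lie in (0, 1]")
    return snps


def write_snps(snps: pd.DataFrame, path: str | Path) -> None:
    snps.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene ontology
# ---------------------------------------------------------------------------

def read_go_edges(path: str | Path) -> nx.DiGraph:
    """Read an is_a edge list TSV (columns child, parent) into a DAG."""
    edges = pd.read_csv(path, sep="\t", dtype=str)
    dag = nx.DiGraph()
    dag.add_edges_from(edges[["child", "parent"]].itertuples(index=False, name=None))
    return dag


def write_go_edges(dag: nx.DiGraph, path: str | Path) -> None:
    rows = sorted(dag.edges())
    pd.DataFrame(rows, columns=["child", "parent"]).to_csv(path, sep="\t", index=False)


def read_obo(path: str | Path) -> nx.DiGraph:
    """Read an OBO ontology, keeping only is_a edges (child -> parent)."""
    import obonet

    graph = obonet.read_obo(str(path))
    dag = nx.DiGraph()
    dag.add_nodes_from(graph.nodes())
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            dag.add_edge(child, parent)
    return dag


def read_gene2term(path: str | Path) -> dict[str, set[str]]:
    """gene -> direct GO term annotations from a two-column TSV."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    mapping: dict[str, set[str]] = {}
    for gene, term in tab[["gene_id", "term_id"]].itertuples(index=False, name=None):
        mapping.setdefault(gene, set()).add(term)
    return mapping


def write_gene2term(mapping: dict[str, set[str]], path: str | Path) -> None:
    rows = sorted((g, t) for g, terms in mapping.items() for t in terms)
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# JSON helpers
# ---------------------------------------------------------------------------

def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
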