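import numpy as np
import pandas as pd
import pytest

from thlineage.containers import ExpressionMatrix
from thlineage.synthetic import SyntheticConfig, generate


def small_config(**overrides) -> SyntheticConfig:
    """A fast, fully featured generating configuration for unit tests."""
    base = dict(
        n_genes=400,
        n_lncrnas=40,
        n_th1_genes=25,
        n_th2_genes=25,
        n_th1_lncrnas=6,
        n_th2_lncrnas=6,
        genome_length=20_000_000,
        n_background_marks=300,
        n_background_snps=300,
        n_cluster_snps=10,
        seed=11,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return generate(small_config())


@pytest.fixture
def two_group_matrix():
    """A 200-feature intensity matrix with two 3-replicate groups."""
    rng = np.random.default_rng(5)
    samples = [f"{g}_r{i}" for g in ("Thp", "Th1") for i in (1, 2, 3)]
    values = pd.DataFrame(
        rng.normal(8, 1, size=(200, 6)),
        index=[f"G{i:03d}" for i in range(200)],
        columns=samples,
    )
    design = pd.DataFrame(
        {
            "sample": samples,
            "group": [s.split("_")[0] for s in samples],
            "replicate": [int(s[-1]) for s in samples],
        }
    )
    return ExpressionMatrix(values=values, design=design, platform_kind="intensity", platform="toy")


def make_annotation(rows):
    """rows: (gene_id, chrom, start, end, strand, biotype)."""
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"]
    ).assign(gene_name=lambda d: d["gene_id"])[
        ["gene_id", "gene_name", "chrom", "start", "end", "strand", "biotype"]
    ]
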