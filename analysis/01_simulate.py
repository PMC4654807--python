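#!/usr/bin/env python
"""Generate the synthetic multi-platform T-helper dataset.

Writes expression matrices for the three platforms (two intensity arrays,
one count platform), the sample sheet, gene/lncRNA annotation (GTF),
lineage-labelled enhancer/promoter marks (BED), the disease-SNP table, the
GO DAG with gene annotations, and the planted ground truth, under
results/data/.
"""

import argparse
from pathlib import Path

from thlineage.synthetic import SyntheticConfig, generate, write_dataset
from thlineage.workflow import stage_seed

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

config = SyntheticConfig(seed=stage_seed(args.seed, "synthetic"))
data = generate(config)
write_dataset(data, args.results / "data")

truth = data.truth
print(f"features: {len(data.genes)} genes + {len(data.lncrnas)} lncRNAs "
      f"on {config.genome_length/1e6:.0f} Mb")
print(f"planted: {len(truth.th1_genes)} Th1 / {len(truth.th2_genes)} Th2 genes, "
      f"{len(truth.th1_lncrnas)} / {len(truth.th2_lncrnas)} lncRNAs "
      f"(log2 effect {config.effect_lfc})")
print(f"planted vicinity pairs: {len(truth.vicinity_pairs)}; "
      f"SNP cluster traits: {', '.join(config.snp_cluster_traits)}")
print(f"wrote {args.results / 'data'}")
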