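#!/usr/bin/env python
"""Classify features as Th1-specific, Th2-specific or neither.

A gene makes the high-confidence list when it is DE on >=2 platforms with
the same fold-change direction, uniquely in the Thp-vs-Th1 (or Thp-vs-Th2)
comparison and not in the Thp-vs-Th0 activation control. Sequencing-only
classification yields the novel gene list and the lncRNA lists.
"""

import argparse
from pathlib import Path

import pandas as pd

from thlineage.lineage import COMPARISONS
from thlineage.synthetic import load_dataset
from thlineage.workflow import PipelineConfig, lineage_stage

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

data = load_dataset(args.results / "data")
out = args.results / "run"
tables = {
    m.platform: {
        comp: pd.read_csv(out / f"de_{m.platform}_{comp}.tsv", sep="\t", index_col=0)
        for comp in COMPARISONS
    }
    for m in data.matrices
}
_, summary = lineage_stage(PipelineConfig(seed=args.seed), data, tables, out)

for name, sizes in summary.items():
    print(f"{name}: {sizes['Th1']} Th1-specific, {sizes['Th2']} Th2-specific")
truth = data.truth
if truth.th1_genes:
    print(f"(planted: {len(truth.th1_genes)} Th1 / {len(truth.th2_genes)} Th2 genes)")
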