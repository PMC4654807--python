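#!/usr/bin/env python
"""Test differential expression for Thp vs Th0/Th1/Th2 on every platform.

Intensity platforms use the moderated (empirical-Bayes) t-test; the count
platform is tested on variance-stabilized normalized counts. Each table is
BH-adjusted and filtered at adj p < 0.05 with |log2FC| > 1, refined by the
presence calls from the previous step (genes only).
"""

import argparse
from pathlib import Path

import pandas as pd

from thlineage.synthetic import load_dataset
from thlineage.workflow import PipelineConfig, de_stage

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

data = load_dataset(args.results / "data")
out = args.results / "run"
pres = {
    m.platform: pd.read_csv(out / f"presence_{m.platform}.tsv", sep="\t", index_col=0)
    for m in data.matrices
}
_, summary = de_stage(PipelineConfig(seed=args.seed), data, pres, {}, out)

for key in sorted(summary):
    print(f"{key}: {summary[key]} DE features")
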