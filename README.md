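# thlineage

Identification and characterization of **Th1- and Th2-lineage-specific
protein-coding genes and lncRNAs** from multi-platform expression data of
differentiating human CD4+ T-helper cells.

Early T-helper polarization is studied with four subtypes — naive
precursors (Thp), activated controls (Th0), and IL12/IL4-polarized cells
(Th1/Th2) — profiled in replicate on array (log2 intensity) and sequencing
(count) platforms. `thlineage` implements the full downstream analysis for
anyone reproducing or extending this design:

1. **Presence calls** — a two-component Gaussian mixture fitted chip-wide
   by EM; a feature is *present* in a subtype iff every replicate favours
   the high-mean component (Illumina-style arrays use detection p < 0.01
   instead). Duplicate probes collapse to the highest-IQR probe.
2. **Differential expression** — moderated t-test with empirical-Bayes
   variance shrinkage on intensities; median-of-ratios normalization +
   log2(x+1) stabilization for counts; DE iff BH-adjusted p < 0.05 and
   |log2FC| > 1, refined by presence calls.
3. **Lineage classification** — consensus across platforms (DE on ≥2
   platforms, same direction); *Th1-specific* = DE in Thp-vs-Th1 only, not
   in the Thp-vs-Th0 activation control, not in Thp-vs-Th2 (and
   symmetrically). Sequencing-only mode yields novel-gene and lncRNA lists.
4. **Epigenetic-mark enrichment** — matching-lineage enhancer (±125 kb of
   TSS) and active-promoter (±2.5 kb) marks counted around each set, with
   an empirical p from 10,000 random same-size gene sets:
   p = (#{null ≥ observed}+1)/(n_iter+1).
5. **lncRNA characterization** — biotype tally; vicinity pairing (5 kb
   upstream / 30 kb downstream of a same-lineage gene) with the pair
   expression trend; guilt-by-association GO annotation via a
   |Pearson r| > 0.9 co-expression network and topology-aware (elim)
   Fisher enrichment, attributing terms with p < 0.01.
6. **Disease-SNP enrichment** — SNPs filtered at p ≤ 1e-5, associated to
   genes within ±100 kb, trait over-representation by the hypergeometric
   upper tail.

A **synthetic-data generator** with planted ground truth (lineage genes and
lncRNAs, vicinity pairs, mark enrichment, SNP clusters, a GO module)
exercises every stage end-to-end without external downloads; see
`docs/methods.md` for the model and its limitations.

## Worked example

The numbered scripts under `analysis/` run the study end-to-end on the
default synthetic dataset (10,000 genes, 200 lncRNAs, 300+300 planted
lineage genes, three platforms, 3 replicates):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_presence_calls.py
python analysis/03_differential_expression.py
python analysis/04_lineage_classification.py
python analysis/05_mark_enrichment.py
python analysis/06_lncrna_characterization.py
python analysis/07_snp_enrichment.py
```

Selected output (seed 1):

```
affy: 7355 features present in >=1 subtype (mixture rule; components 4.03 / 8.99)
...
genes_consensus: 300 Th1-specific, 300 Th2-specific
lncrnas: 30 Th1-specific, 30 Th2-specific
...
genes:Th1:enhancer: observed 4346 vs null mean 1663.7 -> empirical p = 9.999e-05
genes:Th1:promoter: observed 87 vs null mean 19.1 -> empirical p = 9.999e-05
...
vicinity pairs: 16 Th1, 15 Th2
pair expression trend: mean r = 0.885, 100% positive
...
genes:Th1 top traits:
  celiac disease: k=38/192, p=2.68e-16
```

Reading this: the mixture recovered the generator's unexpressed/expressed
components (means 4 and 9); the consensus classification recovered exactly
the 300+300 planted lineage genes and all 60 planted lncRNAs; enhancer
marks around Th1-specific genes (4,346) far exceed random same-size gene
sets (null mean 1,664), giving the smallest reportable empirical p at
10,000 draws (just under 1e-4); vicinity lncRNA–gene pairs co-express
positively; and the SNP trait planted near Th1 genes ranks first by
hypergeometric p.

The same pipeline runs as one command — `thlineage demo --out DIR --seed 1`
— or on your own inputs (expression TSVs + sample sheet, GTF annotation,
BED6 marks, SNP TSV, GO DAG) via `thlineage run --config cfg.yaml --out DIR`.
Identical config and seed reproduce every output byte-for-byte.

## Layout

- `src/thlineage/` — the library: `synthetic`, `presence`, `diffexpr`,
  `lineage`, `genomic`, `lncfun`, `snp`, `workflow`, `io`, `cli`.
- `analysis/` — numbered narrative drivers (thin wrappers over the library).
- `tests/` — unit, property and acceptance tests (pytest + hypothesis).
- `docs/methods.md` — models, parameter choices, generator assumptions,
  limitations.
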