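"""End-to-end orchestration: synthetic data (or loaded inputs) through
presence calling, differential expression, lineage classification, mark
enrichment, lncRNA characterization and SNP enrichment, with one root seed
and a JSON report.

Every stage writes its outputs as plain TSV/JSON under the run directory, so
any stage can be re-run and inspected in isolation. Per-stage seeds are
derived deterministically from the root seed and the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, genomic, io, lineage, lncfun, presence, snp
from .containers import ExpressionMatrix
from .errors import StageError, ValidationError
from .synthetic import SyntheticConfig, SyntheticDataset, generate, load_dataset, write_dataset

log = logging.getLogger("thlineage")

__version__ = "0.1.0"

COMPARISON_PAIRS = [("Thp", "Th0"), ("Thp", "Th1"), ("Thp", "Th2")]


@dataclass
class PipelineConfig:
    """All thresholds, windows and mode flags of the pipeline.

    Defaults are the study's printed values: DE at BH-adjusted p < 0.05 with
    |log2FC| > 1; detection p < 0.01; co-expression |r| > 0.9; GO attribution
    p < 0.01; SNP filter p <= 1e-5; enhancer/promoter windows +/-125 kb and
    +/-2.5 kb around the TSS; lncRNA vicinity 5 kb up / 30 kb down; SNP-gene
    association +/-100 kb; 10,000 randomization draws.
    """

    data_dir: str | None = None
    synthetic: SyntheticConfig | None = None
    de_alpha: float = 0.05
    lfc: float = 1.0
    detection_alpha: float = 0.01
    coexpr_threshold: float = 0.9
    go_alpha: float = 0.01
    snp_p: float = 1e-5
    enhancer_window: int = 125_000
    promoter_window: int = 2_500
    lnc_up: int = 5_000
    lnc_down: int = 30_000
    snp_window: int = 100_000
    n_iter: int = 10_000
    seed: int = 0
    go_algorithm: str = "elim"  # classic | elim
    refinement: str = "either"  # presence refinement rule for gene DE
    refine_lncrnas: bool = False
    dedup_marks: bool = True
    presence_rule: str = "posterior"


_RANGES = {
    "de_alpha": (0.0, 1.0),
    "detection_alpha": (0.0, 1.0),
    "go_alpha": (0.0, 1.0),
    "snp_p": (0.0, 1.0),
    "coexpr_threshold": (0.0, 1.0),
}


def validate_config(raw: dict) -> PipelineConfig:
    """Build a PipelineConfig from a mapping: inject defaults, report every
    violation (with its field path) at once; unknown keys warn only."""
    import warnings

    known = {f.name for f in fields(PipelineConfig)}
    errors: list[str] = []
    kwargs = {}
    for key, value in raw.items():
        if key == "synthetic":
            try:
                kwargs["synthetic"] = (
                    value if isinstance(value, SyntheticConfig) else SyntheticConfig(**value)
                )
                kwargs["synthetic"].validate()
            except (TypeError, ValidationError) as exc:
                errors.append(f"synthetic: {exc}")
            continue
        if key not in known:
            warnings.warn(f"unknown config key {key!r} ignored", stacklevel=2)
            continue
        kwargs[key] = value
    cfg = PipelineConfig(**{k: v for k, v in kwargs.items() if k in known})
    for name, (lo, hi) in _RANGES.items():
        v = getattr(cfg, name)
        if not (lo < v < hi):
            errors.append(f"{name}: must lie in ({lo}, {hi}), got {v}")
    if cfg.n_iter < 1:
        errors.append("n_iter: must be >= 1")
    for name, allowed in (
        ("go_algorithm", ("classic", "elim")),
        ("refinement", ("either", "both", "test", "none")),
        ("presence_rule", ("posterior", "density")),
    ):
        if getattr(cfg, name) not in allowed:
            errors.append(f"{name}: must be one of {allowed}")
    if errors:
        raise ValidationError("; ".join(errors))
    return cfg


def stage_seed(root_seed: int, stage: str) -> int:
    return (int(root_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _config_hash(config: PipelineConfig) -> str:
    d = asdict(config)
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_demo(out_dir: str | Path, seed: int = 1, **synthetic_overrides) -> dict:
    """One-command synthetic demonstration: generate the default dataset and
    run the full pipeline on it."""
    cfg = PipelineConfig(
        synthetic=SyntheticConfig(seed=stage_seed(seed, "synthetic"), **synthetic_overrides),
        seed=seed,
    )
    return run_pipeline(cfg, out_dir)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages; returns (and writes) the report dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        report: dict = {
            "provenance": {
                "version": __version__,
                "seed": config.seed,
                "config_hash": _config_hash(config),
            }
        }
        data = _stage(report, "inputs", lambda: _inputs_stage(config, out))
        pres, vst = _stage(report, "presence", lambda: presence_stage(config, data, out))
        tables = _stage(report, "diffexpr", lambda: de_stage(config, data, pres, vst, out))
        assignments = _stage(report, "lineage", lambda: lineage_stage(config, data, tables, out))
        _stage(report, "marks", lambda: marks_stage(config, data, assignments, out))
        vic = _stage(report, "vicinity", lambda: vicinity_stage(config, data, assignments, vst, out))
        _stage(report, "go", lambda: go_stage(config, data, assignments, pres, vst, out))
        _stage(report, "snp", lambda: snp_stage(config, data, assignments, pres, out))
        if data.truth is not None and (data.truth.th1_genes or data.truth.th2_genes):
            _stage(
                report,
                "evaluation",
                lambda: evaluation_stage(config, data, pres, assignments, vic, out),
            )
        io.write_json(report, out / "report.json")
        return report
    finally:
        log.removeHandler(handler)
        handler.close()


def _stage(report: dict, name: str, fn):
    log.info("stage %s: start", name)
    try:
        result = fn()
    except Exception as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc
    if isinstance(result, tuple) and len(result) == 2 and isinstance(result[1], dict):
        payload, summary = result
    else:
        payload, summary = result, {}
    report[name] = summary
    log.info("stage %s: done %s", name, summary)
    return payload


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _inputs_stage(config: PipelineConfig, out: Path):
    if config.synthetic is not None:
        data = generate(config.synthetic)
        write_dataset(data, out / "data")
    elif config.data_dir is not None:
        data = load_dataset(config.data_dir)
    else:
        raise ValidationError("config needs either a synthetic block or data_dir")
    summary = {
        "n_features": len(data.annotation),
        "n_genes": len(data.genes),
        "n_lncrnas": len(data.lncrnas),
        "platforms": [m.platform for m in data.matrices],
        "n_snps": len(data.snps),
    }
    return data, summary


def presence_stage(config: PipelineConfig, data: SyntheticDataset, out: Path):
    """Present/absent calls per platform.

    Intensity platforms with detection p-values use the detection rule;
    others get a chip-wide EM mixture fit on pooled values (counts are
    variance-stabilized first). Returns (calls per platform, VST matrices
    for count platforms).
    """
    calls: dict[str, pd.DataFrame] = {}
    vst: dict[str, ExpressionMatrix] = {}
    summary: dict = {}
    for m in data.matrices:
        if m.platform in data.detection_p:
            calls[m.platform] = presence.call_presence_detection(
                data.detection_p[m.platform], m.design, alpha=config.detection_alpha
            )
            summary[m.platform] = {"rule": "detection"}
        else:
            target = m
            if m.platform_kind == "count":
                factors = diffexpr.median_of_ratios_size_factors(m.values)
                target = m.with_values(
                    diffexpr.variance_stabilize(m.values, factors), platform_kind="intensity"
                )
                vst[m.platform] = target
            fit = presence.fit_two_component_em(
                target.values.to_numpy().ravel(),
                seed=stage_seed(config.seed, f"presence:{m.platform}"),
            )
            calls[m.platform] = presence.call_presence_mixture(
                target, fit, rule=config.presence_rule
            )
            summary[m.platform] = {
                "rule": "mixture",
                "mean_low": fit.mean_low,
                "mean_high": fit.mean_high,
                "weight_high": fit.weight_high,
                "converged": bool(fit.converged),
            }
        summary[m.platform]["present_any_group"] = int(calls[m.platform].any(axis=1).sum())
        calls[m.platform].to_csv(out / f"presence_{m.platform}.tsv", sep="\t")
    return (calls, vst), summary


def de_stage(config: PipelineConfig, data: SyntheticDataset, pres, vst, out: Path):
    """Per-platform, per-comparison DE tables with BH adjustment, the
    |log2FC|/adjusted-p thresholds, and presence refinement (genes only by
    default)."""
    gene_ids = set(data.genes["gene_id"])
    tables: dict[str, dict[str, pd.DataFrame]] = {}
    summary: dict = {}
    for m in data.matrices:
        per_comp: dict[str, pd.DataFrame] = {}
        for ref, test in COMPARISON_PAIRS:
            if m.platform_kind == "count":
                raw = diffexpr.count_de_test(m, (ref, test))
            else:
                raw = diffexpr.moderated_t_test(m, (ref, test))
            raw["adj_pvalue"] = diffexpr.bh_adjust(raw["pvalue"].to_numpy())
            is_gene = raw.index.isin(gene_ids)
            gene_tab = diffexpr.apply_de_filter(
                raw[is_gene],
                pres[m.platform],
                alpha=config.de_alpha,
                lfc=config.lfc,
                refinement=config.refinement,
            )
            lnc_tab = diffexpr.apply_de_filter(
                raw[~is_gene],
                pres[m.platform] if config.refine_lncrnas else None,
                alpha=config.de_alpha,
                lfc=config.lfc,
                refinement=config.refinement if config.refine_lncrnas else "none",
            )
            tab = pd.concat([gene_tab, lnc_tab]).loc[raw.index]
            per_comp[f"{ref}_vs_{test}"] = tab
            tab.to_csv(out / f"de_{m.platform}_{ref}_vs_{test}.tsv", sep="\t")
            summary[f"{m.platform}:{ref}_vs_{test}"] = int(tab["is_de"].sum())
        tables[m.platform] = per_comp
    return tables, summary


def lineage_stage(config: PipelineConfig, data: SyntheticDataset, tables, out: Path):
    """Consensus classification for genes; sequencing-only classification for
    genes (the "novel" list) and for lncRNAs."""
    gene_ids = set(data.genes["gene_id"])
    lnc_ids = set(data.lncrnas["gene_id"])
    consensus = lineage.build_consensus(tables)
    assign_consensus = lineage.classify_lineage(consensus, evidence_mode="consensus")
    count_platforms = [m.platform for m in data.matrices if m.platform_kind == "count"]
    assignments = {"genes_consensus": assign_consensus[assign_consensus.index.isin(gene_ids)]}
    if count_platforms:
        seq_status = lineage.single_platform_status(tables[count_platforms[0]])
        assign_seq = lineage.classify_lineage(seq_status, evidence_mode="sequencing-only")
        assignments["genes_seqonly"] = assign_seq[assign_seq.index.isin(gene_ids)]
        assignments["lncrnas"] = assign_seq[assign_seq.index.isin(lnc_ids)]
    summary = {}
    for name, frame in assignments.items():
        frame.to_csv(out / f"lineage_{name}.tsv", sep="\t", index_label="feature_id")
        sets = lineage.lineage_sets(frame)
        summary[name] = {"Th1": len(sets["Th1"]), "Th2": len(sets["Th2"])}
    io.write_json(summary, out / "lineage_summary.json")
    return assignments, summary


def marks_stage(config: PipelineConfig, data: SyntheticDataset, assignments, out: Path):
    """Randomization enrichment of matching-lineage enhancer/promoter marks
    around each lineage-specific feature set."""
    results = {}
    feature_sets = {
        "genes": (assignments["genes_consensus"], data.genes),
        "lncrnas": (assignments.get("lncrnas"), data.lncrnas),
    }
    for set_name, (assign, universe) in feature_sets.items():
        if assign is None or universe.empty:
            continue
        universe = universe.set_index("gene_id")
        sets = lineage.lineage_sets(assign)
        for mark_class, marks, window in (
            ("enhancer", data.enhancers, config.enhancer_window),
            ("promoter", data.promoters, config.promoter_window),
        ):
            spec = genomic.WindowSpec(window, window, anchor="tss", strand_aware=False)
            for lin in ("Th1", "Th2"):
                target = universe.loc[sorted(sets[lin] & set(universe.index))]
                lineage_marks = marks[marks["name"] == lin].reset_index(drop=True)
                key = f"{set_name}:{lin}:{mark_class}"
                if target.empty or len(universe) - len(target) < len(target):
                    results[key] = {"observed": 0, "empirical_p": None, "n_iter": 0}
                    continue
                enr = genomic.randomization_enrichment(
                    target,
                    universe,
                    lineage_marks,
                    spec,
                    n_iter=config.n_iter,
                    seed=stage_seed(config.seed, f"marks:{key}"),
                    dedup=config.dedup_marks,
                )
                results[key] = enr.summary()
    io.write_json(results, out / "mark_enrichment.json")
    return results, results


def vicinity_stage(config: PipelineConfig, data, assignments, vst, out: Path):
    """Same-lineage lncRNA-gene vicinity pairs and their expression trend."""
    gene_sets = lineage.lineage_sets(assignments["genes_consensus"])
    lnc_sets = (
        lineage.lineage_sets(assignments["lncrnas"])
        if "lncrnas" in assignments
        else {"Th1": set(), "Th2": set()}
    )
    genes_ix = data.genes.set_index("gene_id")
    lnc_ix = data.lncrnas.set_index("gene_id")
    all_pairs = []
    for lin in ("Th1", "Th2"):
        g = genes_ix.loc[sorted(gene_sets[lin] & set(genes_ix.index))].reset_index()
        l = lnc_ix.loc[sorted(lnc_sets[lin] & set(lnc_ix.index))].reset_index()
        pairs = genomic.lncrna_gene_vicinity(
            l, g, upstream=config.lnc_up, downstream=config.lnc_down
        )
        pairs["lineage"] = lin
        all_pairs.append(pairs)
    pairs = pd.concat(all_pairs, ignore_index=True)
    summary: dict = {
        lin: int((pairs["lineage"] == lin).sum()) for lin in ("Th1", "Th2")
    }
    trend_summary = {}
    expr = next(iter(vst.values())).values if vst else None
    if expr is not None and not pairs.empty:
        trend, trend_summary = lncfun.pair_correlation_trend(pairs, expr, expr)
        trend.to_csv(out / "vicinity_trend.tsv", sep="\t", index=False)
    pairs.to_csv(out / "vicinity_pairs.tsv", sep="\t", index=False)
    summary["trend"] = trend_summary
    return (pairs, trend_summary), summary


def go_stage(config: PipelineConfig, data, assignments, pres, vst, out: Path):
    """Guilt-by-association GO attribution for lineage-specific lncRNAs."""
    if not vst or "lncrnas" not in assignments:
        return {}, {}
    expr = next(iter(vst.values()))
    count_platform = expr.platform
    lnc_sets = lineage.lineage_sets(assignments["lncrnas"])
    lnc_ids = sorted(lnc_sets["Th1"] | lnc_sets["Th2"])
    gene_ids = data.genes["gene_id"]
    present = pres[count_platform].any(axis=1)
    expressed_genes = [g for g in gene_ids if present.get(g, False)]
    if not lnc_ids or not expressed_genes:
        return {}, {"n_lncrnas": 0}
    edges = lncfun.coexpression_network(
        expr.values.loc[lnc_ids],
        expr.values.loc[expressed_genes],
        threshold=config.coexpr_threshold,
    )
    edges.to_csv(out / "coexpression_edges.tsv", sep="\t", index=False)
    attribution = lncfun.attribute_terms_to_lncrnas(
        edges,
        set(expressed_genes),
        data.gene2terms,
        data.go_dag,
        algorithm=config.go_algorithm,
        cutoff=config.go_alpha,
        alpha_elim=config.go_alpha,
    )
    attribution.to_csv(out / "go_attribution.tsv", sep="\t", index=False)
    tally = lncfun.classify_biotype(lnc_ids, data.annotation)
    tally.to_csv(out / "lncrna_biotypes.tsv", sep="\t", header=["count"])
    summary = {
        "n_lncrnas": len(lnc_ids),
        "n_edges": int(len(edges)),
        "n_attributions": int(len(attribution)),
        "biotypes": tally.to_dict(),
    }
    return attribution, summary


def snp_stage(config: PipelineConfig, data, assignments, pres, out: Path):
    """Trait enrichment of disease SNPs in each lineage-specific set."""
    kept = snp.filter_snps(data.snps, threshold=config.snp_p)
    summary: dict = {"n_snps_kept": int(len(kept))}
    results = {}
    count_present = None
    for m in data.matrices:
        if m.platform_kind == "count":
            count_present = pres[m.platform].any(axis=1)
            break
    for set_name, features in (("genes", data.genes), ("lncrnas", data.lncrnas)):
        key_assign = "genes_consensus" if set_name == "genes" else "lncrnas"
        if key_assign not in assignments or features.empty:
            continue
        assoc = snp.associate_genes(kept, features, window=config.snp_window)
        sets = lineage.lineage_sets(assignments[key_assign])
        ids = features["gene_id"]
        if count_present is not None:
            universe = {g for g in ids if count_present.get(g, False)}
        else:
            universe = set(ids)
        for lin in ("Th1", "Th2"):
            lineage_set = sets[lin] & set(ids)
            universe_full = universe | lineage_set
            if not lineage_set:
                continue
            tab = snp.trait_hypergeometric_test(lineage_set, assoc, universe_full)
            tab.to_csv(out / f"snp_traits_{set_name}_{lin}.tsv", sep="\t", index=False)
            results[f"{set_name}:{lin}"] = tab
            top = tab.head(1)
            summary[f"{set_name}:{lin}"] = (
                {"top_trait": top["trait"].iloc[0], "top_p": float(top["pvalue"].iloc[0])}
                if len(top)
                else {}
            )
    return results, summary


def evaluation_stage(config: PipelineConfig, data, pres, assignments, vic, out: Path):
    """Compare recovered structure against the planted ground truth."""
    truth = data.truth
    pairs, _ = vic
    summary: dict = {}

    def f1(found: set, planted: set) -> float:
        if not found and not planted:
            return float("nan")
        tp = len(found & planted)
        prec = tp / len(found) if found else 0.0
        rec = tp / len(planted) if planted else 0.0
        return 2 * prec * rec / (prec + rec) if prec + rec else 0.0

    gene_sets = lineage.lineage_sets(assignments["genes_consensus"])
    summary["th1_gene_f1"] = f1(gene_sets["Th1"], truth.th1_genes)
    summary["th2_gene_f1"] = f1(gene_sets["Th2"], truth.th2_genes)
    if "lncrnas" in assignments:
        lnc_sets = lineage.lineage_sets(assignments["lncrnas"])
        summary["th1_lncrna_f1"] = f1(lnc_sets["Th1"], truth.th1_lncrnas)
        summary["th2_lncrna_f1"] = f1(lnc_sets["Th2"], truth.th2_lncrnas)

    found_pairs = set(map(tuple, pairs[["lncrna_id", "gene_id"]].itertuples(index=False)))
    planted = truth.vicinity_pairs
    summary["vicinity_planted"] = len(planted)
    summary["vicinity_recovered"] = len(planted & found_pairs)

    # presence fidelity on the first mixture-called platform
    for m in data.matrices:
        if m.platform in data.detection_p:
            continue
        calls = pres[m.platform]
        sens, spec = presence_fidelity(calls, truth, data.annotation)
        summary[f"presence_sensitivity_{m.platform}"] = sens
        summary[f"presence_specificity_{m.platform}"] = spec
        break

    # planted SNP trait rank within the matching lineage gene table
    for i, trait in enumerate(data.config.snp_cluster_traits if data.config else []):
        lin = "Th1" if i % 2 == 0 else "Th2"
        path = out / f"snp_traits_genes_{lin}.tsv"
        if path.exists():
            tab = pd.read_csv(path, sep="\t")
            ranks = tab.index[tab["trait"] == trait]
            summary[f"snp_trait_rank:{trait}"] = int(ranks[0]) + 1 if len(ranks) else None

    # planted GO term attribution
    attr_path = out / "go_attribution.tsv"
    if truth.planted_go_term and attr_path.exists():
        attr = pd.read_csv(attr_path, sep="\t")
        hit = attr[
            (attr["lncrna_id"] == truth.planted_go_lncrna)
            & (attr["term_id"] == truth.planted_go_term)
        ]
        summary["planted_go_term_attributed"] = bool(len(hit))
    io.write_json(summary, out / "evaluation.json")
    return summary, summary


def presence_fidelity(calls: pd.DataFrame, truth, annotation) -> tuple[float, float]:
    """Sensitivity/specificity of presence calls vs the planted expressed sets."""
    tp = fp = fn = tn = 0
    for group in calls.columns:
        expressed = truth.expressed_features.get(group, set())
        for fid, call in calls[group].items():
            if fid in expressed:
                tp += call
                fn += not call
            else:
                fp += call
                tn += not call
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return float(sens), float(spec)
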