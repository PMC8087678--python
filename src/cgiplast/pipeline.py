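"""End-to-end orchestration: simulate/load -> curate -> PRC2 -> DE -> classes
-> plasticity, specificity, enrichment and chromatin summaries.

The pipeline consumes either a simulation block (generating the full input
bundle in memory) or a directory of plain-text inputs in the same formats
the generator writes, runs every stage with one set of thresholds, and
produces a results bundle: per-stage TSVs, a summary JSON and a log. All
randomness derives from the single top-level seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cl
from . import simulate as sim
from .chromatin import lad_fraction_by_class
from .classify import ClassThresholds, assemble_gene_classes, call_hypermethylated_promoters
from .diffexpr import compute_fpkm, expression_filter, nb_two_group_test
from .enrichment import (
    binomial_z_enrichment,
    enhancers_per_gene,
    hypergeom_region_enrichment,
    linked_regions_for_genes,
)
from .intervals import read_bed
from .plasticity import cancer_restricted_genes, pca_distance_ratio, plastic_genes
from .prc2 import classify_prc2, gene_prc2_class, normal_expression_gate
from .promoters import (
    PRC2_NEG,
    PRC2_POS,
    curate_promoters,
    map_genes,
    promoter_beta,
    promoters_to_frame,
)

logger = logging.getLogger("cgiplast")


@dataclass
class PipelineThresholds:
    """Every stage cutoff, with its canonical default."""

    upstream: int = 250
    downstream: int = 500
    h3k27me3_states: tuple[int, ...] = (10, 11, 13)
    normal_fpkm_gate: float = 4.0
    detect_frac: float = 0.8
    fpkm_cutoff: float = 1.0
    fpkm_frac: float = 0.5
    padj_cutoff: float = 0.05
    lfc_cutoff: float = 1.0
    beta_low: float = 0.2
    beta_low_frac: float = 0.9
    beta_high: float = 0.3
    beta_high_frac: float = 0.15
    restricted_fc: float = 2.0
    min_normal_samples: int = 5
    motif_fpkm_cutoff: float = 10.0
    motif_p_cutoff: float = 0.01
    set_p_cutoff: float = 0.05

    def class_thresholds(self) -> ClassThresholds:
        return ClassThresholds(
            beta_low=self.beta_low,
            beta_low_frac=self.beta_low_frac,
            beta_high=self.beta_high,
            beta_high_frac=self.beta_high_frac,
            padj_cutoff=self.padj_cutoff,
            lfc_cutoff=self.lfc_cutoff,
        )


@dataclass
class PipelineConfig:
    seed: int = 1
    out_dir: str = "cgiplast_results"
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    input_dir: str | None = None  # alternative to `simulate`
    thresholds: PipelineThresholds = field(default_factory=PipelineThresholds)
    write_fixture: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        th = PipelineThresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=th, **raw)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return findings: strings prefixed ERROR/WARNING; empty = all defaults ok."""
    findings: list[str] = []
    th = config.thresholds
    defaults = PipelineThresholds()
    for f in dataclasses.fields(PipelineThresholds):
        v, d = getattr(th, f.name), getattr(defaults, f.name)
        if f.name.endswith("_frac") and not (0 <= v <= 1):
            findings.append(f"ERROR: {f.name}={v} outside [0, 1]")
        elif v != d:
            note = " (robustness setting)" if f.name == "fpkm_cutoff" else ""
            findings.append(f"WARNING: non-default {f.name}={v} (default {d}){note}")
    if config.input_dir is None and not isinstance(config.simulate, dict):
        findings.append("ERROR: need either input_dir or a simulate block")
    if config.input_dir is not None and not Path(config.input_dir).exists():
        findings.append(f"ERROR: input_dir {config.input_dir} does not exist")
    try:
        sim.SimulationConfig(**{"seed": config.seed, **config.simulate}).validate()
    except (TypeError, sim.ConfigError) as exc:
        findings.append(f"ERROR: invalid simulate block: {exc}")
    return findings


def load_fixture(in_dir) -> tuple[sim.AnnotationBundle, dict[str, sim.CohortBundle], sim.TruthTable | None]:
    """Read an input bundle from the plain-text fixture layout."""
    d = Path(in_dir)
    tss = pd.read_csv(d / "tss_table.tsv", sep="\t")
    probes = pd.read_csv(d / "probe_manifest.tsv", sep="\t")
    links = pd.read_csv(d / "enhancer_links.tsv", sep="\t")
    motifs = {
        p.stem.removeprefix("motifs_"): read_bed(p) for p in sorted(d.glob("motifs_*.bed"))
    }
    gene_sets = {}
    gmt = d / "gene_sets.gmt"
    if gmt.exists():
        for line in gmt.read_text().splitlines():
            parts = line.rstrip("\n").split("\t")
            if len(parts) > 2:
                gene_sets[parts[0]] = parts[2:]
    samples = pd.read_csv(d / "samples.tsv", sep="\t")
    lengths = pd.read_csv(d / "gene_lengths.tsv", sep="\t").set_index("gene_id")["length"]
    cohorts = {}
    for ct, meta in samples.groupby("cancer_type"):
        cohorts[ct] = sim.CohortBundle(
            cancer_type=ct,
            counts=pd.read_csv(d / f"counts_{ct}.tsv", sep="\t", index_col=0),
            beta=pd.read_csv(d / f"beta_{ct}.tsv", sep="\t", index_col=0),
            samples=meta.reset_index(drop=True),
            gene_lengths=lengths.astype(float),
        )
    manifest_tf = {}
    manifest = d / "manifest.json"
    if manifest.exists():
        manifest_tf = json.loads(manifest.read_text()).get("tf_genes", {})
    annotation = sim.AnnotationBundle(
        tss_table=tss,
        probe_manifest=probes,
        cgi=read_bed(d / "cgi.bed"),
        chrom_states=read_bed(d / "chrom_states.bed"),
        ezh2_peaks=read_bed(d / "ezh2_peaks.bed"),
        suz12_peaks=read_bed(d / "suz12_peaks.bed"),
        lads=read_bed(d / "lads.bed"),
        enhancer_links=links,
        motif_occurrences=motifs,
        gene_sets=gene_sets,
        tf_genes=manifest_tf,
        gene_meta=pd.DataFrame(),
        planted=pd.DataFrame(),
        cancer_types=sorted(cohorts),
    )
    truth = None
    if (d / "truth_labels.tsv").exists():
        truth = sim.TruthTable(
            labels=pd.read_csv(d / "truth_labels.tsv", sep="\t", index_col=0),
            flags=pd.read_csv(d / "truth_flags.tsv", sep="\t", index_col=0),
        )
    return annotation, cohorts, truth


def analyze(
    annotation: sim.AnnotationBundle,
    cohorts: dict[str, sim.CohortBundle],
    thresholds: PipelineThresholds | None = None,
) -> dict:
    """Run every analysis stage in memory; returns a dict of result tables."""
    th = thresholds or PipelineThresholds()
    t0 = time.time()

    promoters = curate_promoters(
        annotation.tss_table,
        annotation.probe_manifest,
        annotation.cgi,
        upstream=th.upstream,
        downstream=th.downstream,
    )
    promoters = classify_prc2(
        promoters,
        annotation.chrom_states,
        annotation.ezh2_peaks,
        annotation.suz12_peaks,
        th.h3k27me3_states,
    )
    gene_class = gene_prc2_class(promoters)
    logger.info("curated %d CGI promoters (%.1fs)", len(promoters), time.time() - t0)

    all_calls = []
    per_type: dict[str, dict] = {}
    tumor_fpkm_frames = []
    tumor_type_labels = {}
    for ct, bundle in cohorts.items():
        samples = bundle.samples
        normal_ids = list(samples.loc[samples["condition"] == "normal", "sample_id"])
        tumor_ids = list(samples.loc[samples["condition"] == "tumor", "sample_id"])
        if len(normal_ids) < th.min_normal_samples:
            logger.warning(
                "skipping %s: %d nonmalignant samples (< %d)",
                ct, len(normal_ids), th.min_normal_samples,
            )
            continue
        fpkm = compute_fpkm(bundle.counts, bundle.gene_lengths)
        passed = expression_filter(
            bundle.counts, fpkm, normal_ids, tumor_ids,
            th.detect_frac, th.fpkm_cutoff, th.fpkm_frac,
        )
        de = nb_two_group_test(bundle.counts, normal_ids, tumor_ids, passed)
        prc2_pos_genes = [g for g, c in gene_class.items() if c == PRC2_POS]
        gated = normal_expression_gate(prc2_pos_genes, fpkm, normal_ids, th.normal_fpkm_gate)
        pbeta = promoter_beta(promoters, bundle.beta)
        hyper = call_hypermethylated_promoters(
            pbeta, normal_ids, tumor_ids,
            th.beta_low, th.beta_low_frac, th.beta_high, th.beta_high_frac,
        )
        calls = assemble_gene_classes(
            hyper, de, promoters, gated, ct, th.class_thresholds()
        )
        all_calls.append(calls)
        tumor_fpkm_frames.append(fpkm[tumor_ids])
        for s in tumor_ids:
            tumor_type_labels[s] = ct
        per_type[ct] = {
            "de": de, "fpkm": fpkm, "hyper": hyper, "calls": calls,
            "normal_ids": normal_ids, "tumor_ids": tumor_ids, "gated": gated,
        }
        logger.info("%s: %d class calls (%.1fs)", ct, len(calls), time.time() - t0)

    calls = pd.concat(all_calls, ignore_index=True)
    tumor_fpkm = pd.concat(tumor_fpkm_frames, axis=1)
    tumor_types = pd.Series(tumor_type_labels)

    results: dict = {
        "promoters": promoters,
        "promoter_table": promoters_to_frame(promoters),
        "gene_prc2_class": gene_class,
        "class_calls": calls,
        "per_type": per_type,
    }

    # cross-cancer statistics
    if len(per_type) >= 2:
        results["plasticity"] = plastic_genes(calls)
        restricted = {}
        for ct, state in per_type.items():
            up_genes = calls.loc[
                (calls["cancer_type"] == ct) & (calls["label"] == cl.UP_PRC2), "gene_id"
            ]
            counts_all = pd.concat(
                [cohorts[c].counts[state2["tumor_ids"]] for c, state2 in per_type.items()],
                axis=1,
            )
            restricted[ct] = cancer_restricted_genes(
                tumor_fpkm, tumor_types, list(up_genes), ct,
                th.restricted_fc, counts=counts_all,
            )
        results["restricted"] = restricted

        ratios = {}
        for label in (cl.UP_PRC2, cl.UP_PRC2NEG, cl.HYPER_PRC2):
            genes = sorted(set(calls.loc[calls["label"] == label, "gene_id"]))
            if len(genes) >= 3:
                ratios[label] = pca_distance_ratio(tumor_fpkm, tumor_types, genes)
        results["pca_distance_ratio"] = ratios

    # chromatin summaries: promoter LAD fractions per class (pooled types)
    prom_by_id = {p.promoter_id: p for p in promoters}
    gene_to_prom, _ = map_genes(promoters)
    proms_by_class = {}
    for label in (cl.HYPER_PRC2, cl.UP_PRC2, cl.UP_PRC2NEG):
        genes = set(calls.loc[calls["label"] == label, "gene_id"])
        ivs = {
            pid for g in genes for pid in gene_to_prom.get(g, [])
        }
        proms_by_class[label] = [prom_by_id[pid].interval for pid in sorted(ivs)]
    results["lad_fractions"] = lad_fraction_by_class(proms_by_class, annotation.lads)

    # enhancer links by PRC2 gene class
    class_sets = {
        "PRC2_POS": [g for g, c in gene_class.items() if c == PRC2_POS],
        "PRC2_NEG": [g for g, c in gene_class.items() if c == PRC2_NEG],
    }
    results["enhancers_per_gene"] = enhancers_per_gene(
        annotation.enhancer_links, class_sets
    )

    # reciprocal gene-set enrichment (upregulated PRC2+ vs PRC2- genes, pooled)
    fg = set(calls.loc[calls["label"] == cl.UP_PRC2, "gene_id"])
    bg = set(calls.loc[calls["label"] == cl.UP_PRC2NEG, "gene_id"]) - fg
    if fg and bg and annotation.gene_sets:
        results["set_enrichment"] = binomial_z_enrichment(
            sorted(fg), sorted(bg), annotation.gene_sets, th.set_p_cutoff
        )

    # motif enrichment in linked enhancers (foreground: upregulated PRC2+)
    if fg and bg and annotation.motif_occurrences:
        fg_regions = linked_regions_for_genes(annotation.enhancer_links, sorted(fg))
        bg_regions = linked_regions_for_genes(annotation.enhancer_links, sorted(bg))
        tf_fpkm = {}
        for tf, gene in annotation.tf_genes.items():
            if gene in tumor_fpkm.index:
                tf_fpkm[tf] = float(tumor_fpkm.loc[gene].median())
        if fg_regions and bg_regions and tf_fpkm:
            enriched, table = hypergeom_region_enrichment(
                fg_regions, bg_regions, annotation.motif_occurrences, tf_fpkm,
                th.motif_fpkm_cutoff, th.motif_p_cutoff,
            )
            results["motif_enrichment"] = table
            results["enriched_tfs"] = enriched

    logger.info("analysis finished (%.1fs)", time.time() - t0)
    return results


def compare_to_truth(calls: pd.DataFrame, truth: sim.TruthTable) -> pd.DataFrame:
    """Per-class sensitivity and precision of the calls vs the planted truth."""
    rows = []
    long_truth = (
        truth.labels.rename_axis("gene_id")
        .reset_index()
        .melt(id_vars="gene_id", var_name="cancer_type", value_name="truth")
    )
    merged = calls.merge(long_truth, on=["gene_id", "cancer_type"], how="outer")
    merged["label"] = merged["label"].fillna(cl.NONE)
    merged["truth"] = merged["truth"].fillna(cl.NONE)
    for label in (cl.HYPER_PRC2, cl.UP_PRC2, cl.UP_PRC2NEG):
        tp = ((merged["label"] == label) & (merged["truth"] == label)).sum()
        fp = ((merged["label"] == label) & (merged["truth"] != label)).sum()
        fn = ((merged["label"] != label) & (merged["truth"] == label)).sum()
        rows.append(
            {
                "label": label,
                "tp": int(tp),
                "fp": int(fp),
                "fn": int(fn),
                "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                "precision": tp / (tp + fp) if tp + fp else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("label")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline per the config and write the results bundle."""
    findings = validate_config(config)
    errors = [f for f in findings if f.startswith("ERROR")]
    for f in findings:
        (logger.error if f.startswith("ERROR") else logger.warning)(f)
    if errors:
        raise ValueError("; ".join(errors))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        truth = None
        if config.input_dir is not None:
            annotation, cohorts, truth = load_fixture(config.input_dir)
        else:
            sim_cfg = sim.SimulationConfig(**{"seed": config.seed, **config.simulate})
            annotation, cohorts, truth = sim.simulate_all(sim_cfg)
            if config.write_fixture:
                sim.write_fixture(sim_cfg, annotation, cohorts, truth, out / "fixture")

        results = analyze(annotation, cohorts, config.thresholds)

        results["promoter_table"].to_csv(out / "promoters.tsv", sep="\t", index=False)
        results["class_calls"].to_csv(out / "class_calls.tsv", sep="\t", index=False)
        for ct, state in results["per_type"].items():
            state["de"].rename_axis("gene_id").to_csv(out / f"de_{ct}.tsv", sep="\t")
        if "set_enrichment" in results:
            results["set_enrichment"].to_csv(out / "set_enrichment.tsv", sep="\t", index=False)
        if "motif_enrichment" in results:
            results["motif_enrichment"].to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)

        summary: dict = {
            "n_promoters": len(results["promoters"]),
            "class_counts": {
                ct: results["class_calls"]
                .loc[results["class_calls"]["cancer_type"] == ct, "label"]
                .value_counts()
                .to_dict()
                for ct in results["per_type"]
            },
            "lad_fractions": results["lad_fractions"],
            "enhancers_per_gene": results["enhancers_per_gene"],
        }
        if "plasticity" in results:
            summary["plasticity"] = {
                k: v.per_type.to_dict(orient="records")
                for k, v in results["plasticity"].items()
            }
            summary["pca_distance_ratio"] = results.get("pca_distance_ratio", {})
            summary["restricted_counts"] = {
                ct: len(v) for ct, v in results.get("restricted", {}).items()
            }
        if "enriched_tfs" in results:
            summary["enriched_tfs"] = results["enriched_tfs"]
        if truth is not None and truth.labels.size:
            perf = compare_to_truth(results["class_calls"], truth)
            summary["truth_comparison"] = perf.reset_index().to_dict(orient="records")
            results["truth_comparison"] = perf

        def _clean(o):
            if isinstance(o, dict):
                return {k: _clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [_clean(v) for v in o]
            if isinstance(o, (np.floating, float)):
                return None if np.isnan(o) else float(o)
            if isinstance(o, np.integer):
                return int(o)
            return o

        with open(out / "summary.json", "w") as fh:
            json.dump(_clean(summary), fh, indent=2, sort_keys=True)
        with open(out / "effective_config.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "seed": config.seed,
                    "out_dir": str(config.out_dir),
                    "input_dir": config.input_dir,
                    "simulate": config.simulate,
                    "thresholds": asdict(config.thresholds),
                },
                fh,
            )
        results["summary"] = summary
        return results
    finally:
        logger.removeHandler(handler)
        handler.close()
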