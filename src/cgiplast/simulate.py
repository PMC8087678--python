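"""Synthetic multi-cancer cohort with planted CGI-promoter regulation classes.

The generator emits the same file shapes the real analysis consumes — a TSS
table, CpG-island and chromatin-state BEDs, PRC2-subunit peak BEDs, a
methylation probe manifest, per-cancer-type count and beta matrices, LADs,
enhancer-to-gene links, per-TF motif occurrences and gene-set GMTs — with a
known truth table: which genes are promoter-hypermethylated, which are
upregulated (with or without PRC2 occupancy), which are plastic
(upregulated in one cancer type, hypermethylated in another) and which are
restricted to a single cancer type.

Counts are negative-binomial with sample-specific library sizes; methylation
is simulated at probe level (beta-distributed) so the probe-to-promoter
averaging code path is exercised.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, write_bed

HYPER_PRC2 = "HYPER_PRC2"
UP_PRC2 = "UP_PRC2"
UP_PRC2NEG = "UP_PRC2NEG"
HYPER_PRC2NEG = "HYPER_PRC2NEG"
NONE = "NONE"


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the default study conditions."""

    seed: int = 1
    n_cancer_types: int = 3
    n_normal: int = 10
    n_tumor: int = 40
    n_genes: int = 2000
    # per-gene transcript lengths drawn log-uniformly from this range (bp)
    gene_length_min: int = 500
    gene_length_max: int = 5000
    library_size_mean: float = 3e7
    # background transcriptome: highly expressed genes without promoter
    # annotation that absorb the remaining library mass, so that FPKM values
    # of the annotated genes are on their natural scale
    n_filler_genes: int = 300
    filler_length: int = 20_000
    nb_dispersion: float = 0.05  # var = mu + alpha * mu^2
    # beta-distribution parameters for probe methylation levels
    beta_unmeth: tuple[float, float] = (2.0, 30.0)  # mean ~ 0.06
    beta_meth: tuple[float, float] = (20.0, 6.0)  # mean ~ 0.77
    # planted fractions of the gene universe
    f_hyper_prc2: float = 0.10
    f_up_prc2: float = 0.10
    f_up_prc2neg: float = 0.10
    f_plastic: float = 0.03
    f_restricted: float = 0.05  # flagged subset of the UP_PRC2 plantings
    # effect sizes
    fc_up_prc2: float = 4.0
    fc_up_prc2neg: float = 2.5
    hyper_downreg: float = 0.7  # tumour expression multiplier for hyper genes
    hyper_penetrance: float = 0.4  # fraction of tumours whose beta shifts
    # promoter annotation structure
    prc2_fraction: float = 0.30
    prc2_ambiguous_fraction: float = 0.02
    non_cgi_fraction: float = 0.02
    # LAD membership probabilities by planted class
    lad_frac_hyper: float = 0.40
    lad_frac_up: float = 0.15
    lad_frac_other: float = 0.05
    # enhancer-to-gene links (Poisson means)
    enh_mean_prc2_pos: float = 2.9
    enh_mean_prc2_neg: float = 1.9
    motif_background_rate: float = 0.05
    # baseline expression (FPKM) ranges
    baseline_fpkm_prc2_pos: tuple[float, float] = (0.5, 2.5)
    baseline_fpkm_prc2_neg: tuple[float, float] = (2.0, 32.0)
    # shared expression program in the first cancer type's tumours
    program_gene_frac: float = 0.10
    program_sd: float = 0.25
    # TF-coupling program (quintile analysis); applied in the first type
    n_tf_targets: int = 30
    tf_coupling: float = 0.8
    tf_latent_sd: float = 0.5
    tf_baseline_fpkm: float = 30.0

    def validate(self) -> None:
        planted = self.f_hyper_prc2 + self.f_up_prc2 + self.f_plastic
        if planted > self.prc2_fraction:
            raise ConfigError(
                "PRC2+ plantings exceed the PRC2+ gene fraction "
                f"({planted:.3f} > {self.prc2_fraction:.3f})"
            )
        if self.f_up_prc2neg > 1 - self.prc2_fraction:
            raise ConfigError("f_up_prc2neg exceeds the PRC2- gene fraction")
        for name in (
            "f_hyper_prc2",
            "f_up_prc2",
            "f_up_prc2neg",
            "f_plastic",
            "f_restricted",
            "hyper_penetrance",
            "prc2_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        for name in ("n_cancer_types", "n_normal", "n_tumor", "n_genes"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnnotationBundle:
    tss_table: pd.DataFrame  # tss_id, gene_id, chrom, position (1-based), strand
    probe_manifest: pd.DataFrame  # probe_id, chrom, position (1-based)
    cgi: list[GenomicInterval]
    chrom_states: list[GenomicInterval]  # name carries the state label
    ezh2_peaks: list[GenomicInterval]
    suz12_peaks: list[GenomicInterval]
    lads: list[GenomicInterval]
    enhancer_links: pd.DataFrame  # peak_id, chrom, start, end, gene_id, correlation
    motif_occurrences: dict[str, list[GenomicInterval]]
    gene_sets: dict[str, list[str]]
    tf_genes: dict[str, str]  # TF name -> gene_id carrying its expression
    gene_meta: pd.DataFrame  # per gene: length, prc2 planting, cgi flag
    planted: pd.DataFrame  # per gene: role, target types (internal truth seed)
    cancer_types: list[str]


@dataclass
class TruthTable:
    """Planted (gene, cancer type) labels plus global plastic/restricted flags."""

    labels: pd.DataFrame  # genes x cancer types, values in the label vocabulary
    flags: pd.DataFrame  # per gene: plastic, restricted booleans
    tf_targets: dict[str, list[str]] = field(default_factory=dict)

    def genes_with_label(self, label: str, cancer_type: str) -> list[str]:
        col = self.labels[cancer_type]
        return list(col.index[col == label])


@dataclass
class CohortBundle:
    cancer_type: str
    counts: pd.DataFrame  # genes x samples, integer counts
    beta: pd.DataFrame  # probes x samples in [0, 1]
    samples: pd.DataFrame  # sample_id, cancer_type, condition
    gene_lengths: pd.Series


def _plant_roles(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign every gene a PRC2 planting and (possibly) a class role."""
    n = config.n_genes
    genes = [f"G{i:05d}" for i in range(n)]
    n_pos = int(round(config.prc2_fraction * n))
    n_amb = int(round(config.prc2_ambiguous_fraction * n))
    prc2 = np.array(["neg"] * n, dtype=object)
    order = rng.permutation(n)
    prc2[order[:n_pos]] = "pos"
    prc2[order[n_pos : n_pos + n_amb]] = "ambiguous"

    roles = np.array(["none"] * n, dtype=object)
    type_a = np.full(n, -1)  # primary planted type (UP type for plastic)
    type_b = np.full(n, -1)  # secondary type (HYPER type for plastic)
    pos_idx = list(order[:n_pos])
    neg_idx = [i for i in order[n_pos + n_amb :]]

    n_hyper = int(round(config.f_hyper_prc2 * n))
    n_up = int(round(config.f_up_prc2 * n))
    n_plastic = int(round(config.f_plastic * n))
    n_upneg = int(round(config.f_up_prc2neg * n))

    take_pos = pos_idx[: n_hyper + n_up + n_plastic]
    hyper_idx = take_pos[:n_hyper]
    up_idx = take_pos[n_hyper : n_hyper + n_up]
    plastic_idx = take_pos[n_hyper + n_up :]
    upneg_idx = neg_idx[:n_upneg]

    k = config.n_cancer_types
    roles[hyper_idx] = "hyper_prc2"
    type_a[hyper_idx] = rng.integers(0, k, size=len(hyper_idx))
    roles[up_idx] = "up_prc2"
    type_a[up_idx] = rng.integers(0, k, size=len(up_idx))
    roles[upneg_idx] = "up_prc2neg"
    type_a[upneg_idx] = rng.integers(0, k, size=len(upneg_idx))
    roles[plastic_idx] = "plastic"
    type_a[plastic_idx] = rng.integers(0, k, size=len(plastic_idx))
    shift = rng.integers(1, k, size=len(plastic_idx))
    type_b[plastic_idx] = (type_a[plastic_idx] + shift) % k

    restricted = np.zeros(n, dtype=bool)
    n_restricted = min(int(round(config.f_restricted * n)), len(up_idx))
    restricted[up_idx[:n_restricted]] = True

    return pd.DataFrame(
        {
            "gene_id": genes,
            "prc2": prc2,
            "role": roles,
            "type_a": type_a,
            "type_b": type_b,
            "restricted": restricted,
        }
    ).set_index("gene_id")


def simulate_annotation(config: SimulationConfig) -> AnnotationBundle:
    """Build the toy genome annotation with planted PRC2/CGI/LAD structure."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    planted = _plant_roles(config, rng)
    genes = list(planted.index)
    n = len(genes)
    cancer_types = [f"CT{i + 1:02d}" for i in range(config.n_cancer_types)]

    lengths = np.exp(
        rng.uniform(
            np.log(config.gene_length_min), np.log(config.gene_length_max), size=n
        )
    ).astype(int)

    chroms = np.where(np.arange(n) % 2 == 0, "chr1", "chr2")
    base = 20_000 + (np.arange(n) // 2) * 8_000  # gene anchor position (0-based)
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    # which genes lack a CGI (drawn from the unplanted pool only)
    none_pool = np.flatnonzero((planted["role"] == "none").to_numpy())
    n_noncgi = int(round(config.non_cgi_fraction * n))
    non_cgi = set(rng.choice(none_pool, size=min(n_noncgi, len(none_pool)), replace=False))

    tss_rows, probe_rows = [], []
    cgi, states, ezh2, suz12, lads = [], [], [], [], []
    state_labels = ["10_TssBiv", "11_BivFlnk", "13_ReprPC"]
    probe_counter = 0

    for i, gene in enumerate(genes):
        chrom, b, strand = chroms[i], int(base[i]), strands[i]
        # 1-3 TSSs clustered within +/-100 bp share one probe set (merged later)
        n_tss = int(rng.integers(1, 4))
        offsets = [0] + list(rng.integers(-100, 101, size=n_tss - 1))
        anchors = [(b + off, "m") for off in offsets]
        # some genes get a distal second promoter with its own probes
        has_distal = rng.random() < 0.25
        if has_distal:
            anchors.append((b + 2000, "d"))
        for j, (pos, _tag) in enumerate(anchors):
            tss_rows.append((f"T{i:05d}_{j}", gene, chrom, pos + 1, strand))
        # probes: main cluster inside every clustered window, distal separate
        for tag, lo, hi in (("m", b - 40, b + 140), ("d", b + 1950, b + 2100)):
            if tag == "d" and not has_distal:
                continue
            n_probes = int(rng.integers(2, 7))
            positions = np.sort(rng.integers(lo, hi + 1, size=n_probes))
            for p in positions:
                probe_rows.append((f"cg{probe_counter:07d}", chrom, int(p) + 1))
                probe_counter += 1
        if i not in non_cgi:
            cgi.append(GenomicInterval(chrom, b - 300, b + 400, name=f"CGI_{gene}"))
            if has_distal:
                cgi.append(
                    GenomicInterval(chrom, b + 1900, b + 2200, name=f"CGI_{gene}_d")
                )
        prc2 = planted.at[gene, "prc2"]
        span = (b - 300, b + 2300 if has_distal else b + 600)
        if prc2 in ("pos", "ambiguous"):
            label = state_labels[int(rng.integers(0, 3))]
            states.append(GenomicInterval(chrom, span[0], span[1], name=label))
        else:
            states.append(GenomicInterval(chrom, b - 200, b + 400, name="1_TssA"))
        if prc2 == "pos":
            peak = GenomicInterval(chrom, b - 250, b + 2250 if has_distal else b + 350)
            (ezh2 if rng.random() < 0.5 else suz12).append(peak)
        # LAD placement by planted class
        role = planted.at[gene, "role"]
        if role == "hyper_prc2":
            p_lad = config.lad_frac_hyper
        elif role in ("up_prc2", "plastic"):
            p_lad = config.lad_frac_up
        else:
            p_lad = config.lad_frac_other
        if rng.random() < p_lad:
            # the LAD covers every promoter of the gene, distal included
            lad_end = b + 2600 if has_distal else b + 1000
            lads.append(GenomicInterval(chrom, b - 1000, lad_end, name=f"LAD_{gene}"))

    tss_table = pd.DataFrame(
        tss_rows, columns=["tss_id", "gene_id", "chrom", "position", "strand"]
    )
    probe_manifest = pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "position"])

    # enhancer-to-gene links: more links for PRC2+ genes
    link_rows = []
    enh_by_gene: dict[str, list[GenomicInterval]] = {}
    for i, gene in enumerate(genes):
        mean = (
            config.enh_mean_prc2_pos
            if planted.at[gene, "prc2"] == "pos"
            else config.enh_mean_prc2_neg
        )
        n_links = int(rng.poisson(mean))
        enh_by_gene[gene] = []
        for j in range(n_links):
            offset = int(rng.integers(10_000, 40_000)) * (1 if rng.random() < 0.5 else -1)
            s = max(int(base[i]) + offset, 0)
            iv = GenomicInterval(chroms[i], s, s + 400, name=f"enh_{gene}_{j}")
            enh_by_gene[gene].append(iv)
            corr = float(rng.uniform(0.3, 0.9))
            link_rows.append((iv.name, iv.chrom, iv.start, iv.end, gene, round(corr, 3)))
    enhancer_links = pd.DataFrame(
        link_rows, columns=["peak_id", "chrom", "start", "end", "gene_id", "correlation"]
    )

    # motif occurrences: TF_A planted in enhancers of UP_PRC2 genes, TF_B in
    # enhancers of UP_PRC2NEG genes, plus a uniform background rate
    up_pos = [g for g in genes if planted.at[g, "role"] in ("up_prc2", "plastic")]
    up_neg = [g for g in genes if planted.at[g, "role"] == "up_prc2neg"]
    tf_target_map = {
        "TF_A": list(rng.choice(up_pos, size=len(up_pos) // 2, replace=False)),
        "TF_B": list(rng.choice(up_neg, size=len(up_neg) // 2, replace=False)),
    }
    motif_occurrences: dict[str, list[GenomicInterval]] = {}
    for tf, targets in tf_target_map.items():
        occs = []
        target_set = set(targets)
        for gene, enhs in enh_by_gene.items():
            for iv in enhs:
                hit = gene in target_set or rng.random() < config.motif_background_rate
                if hit:
                    pos = int(rng.integers(iv.start, iv.end - 12))
                    occs.append(GenomicInterval(iv.chrom, pos, pos + 12, name=tf))
        motif_occurrences[tf] = occs

    # gene sets: one enriched in each upregulated class, plus random sets
    def _sample(pool, k):
        return list(rng.choice(pool, size=min(k, len(pool)), replace=False))

    gene_sets = {
        "PATHWAY_PRC2POS_LIKE": sorted(_sample(up_pos, 60) + _sample(genes, 30)),
        "PATHWAY_PRC2NEG_LIKE": sorted(_sample(up_neg, 60) + _sample(genes, 30)),
        "PATHWAY_RANDOM_1": sorted(_sample(genes, 80)),
        "PATHWAY_RANDOM_2": sorted(_sample(genes, 80)),
    }

    # TF driver genes for the expression-quintile analysis: two highly
    # expressed PRC2- genes carry TF_A / TF_B expression
    driver_pool = [g for g in genes if planted.at[g, "role"] == "none"
                   and planted.at[g, "prc2"] == "neg"]
    tf_genes = {"TF_A": driver_pool[0], "TF_B": driver_pool[1]}

    gene_meta = pd.DataFrame(
        {
            "gene_id": genes,
            "length": lengths,
            "chrom": chroms,
            "anchor": base,
            "strand": strands,
            "prc2": planted["prc2"].to_numpy(),
            "is_cgi": [i not in non_cgi for i in range(n)],
        }
    ).set_index("gene_id")

    return AnnotationBundle(
        tss_table=tss_table,
        probe_manifest=probe_manifest,
        cgi=cgi,
        chrom_states=states,
        ezh2_peaks=ezh2,
        suz12_peaks=suz12,
        lads=lads,
        enhancer_links=enhancer_links,
        motif_occurrences=motif_occurrences,
        gene_sets=gene_sets,
        tf_genes=tf_genes,
        gene_meta=gene_meta,
        planted=planted,
        cancer_types=cancer_types,
    )


def _truth_from_planted(annotation: AnnotationBundle) -> TruthTable:
    planted = annotation.planted
    types = annotation.cancer_types
    labels = pd.DataFrame(NONE, index=planted.index, columns=types)
    for gene, row in planted.iterrows():
        if row["role"] == "hyper_prc2":
            labels.at[gene, types[row["type_a"]]] = HYPER_PRC2
        elif row["role"] == "up_prc2":
            labels.at[gene, types[row["type_a"]]] = UP_PRC2
        elif row["role"] == "up_prc2neg":
            labels.at[gene, types[row["type_a"]]] = UP_PRC2NEG
        elif row["role"] == "plastic":
            labels.at[gene, types[row["type_a"]]] = UP_PRC2
            labels.at[gene, types[row["type_b"]]] = HYPER_PRC2
    flags = pd.DataFrame(
        {
            "plastic": planted["role"] == "plastic",
            "restricted": planted["restricted"],
        },
        index=planted.index,
    )
    tf_targets = {}  # filled by simulate_cohort (TF program targets)
    return TruthTable(labels=labels, flags=flags, tf_targets=tf_targets)


def simulate_cohort(
    config: SimulationConfig, annotation: AnnotationBundle
) -> tuple[dict[str, CohortBundle], TruthTable]:
    """Draw count and beta matrices per cancer type around the planted truth."""
    rng = np.random.default_rng(config.seed + 1)
    planted = annotation.planted
    genes = list(planted.index)
    n = len(genes)
    meta = annotation.gene_meta
    lengths = meta["length"].astype(float)
    types = annotation.cancer_types
    truth = _truth_from_planted(annotation)

    # baseline FPKM by PRC2 planting; TF driver genes overridden to high level
    lo_p, hi_p = config.baseline_fpkm_prc2_pos
    lo_n, hi_n = config.baseline_fpkm_prc2_neg
    is_pos_like = (planted["prc2"] != "neg").to_numpy()
    baseline_fpkm = np.where(
        is_pos_like,
        rng.uniform(lo_p, hi_p, size=n),
        np.exp(rng.uniform(np.log(lo_n), np.log(hi_n), size=n)),
    )
    gene_pos = {g: i for i, g in enumerate(genes)}
    for tf, gene in annotation.tf_genes.items():
        baseline_fpkm[gene_pos[gene]] = config.tf_baseline_fpkm

    # per-gene expected rate at the mean library size; filler genes take up
    # the rest of the 1e9 FPKM*length budget so realized FPKM ~= baseline
    base_rate = baseline_fpkm * lengths.to_numpy() * config.library_size_mean / 1e9
    filler_ids = [f"FILLER{i:04d}" for i in range(config.n_filler_genes)]
    budget = 1e9 - float((baseline_fpkm * lengths.to_numpy()).sum())
    filler_fpkm = max(budget, 0.0) / (config.n_filler_genes * config.filler_length)
    filler_rate = np.full(
        config.n_filler_genes,
        filler_fpkm * config.filler_length * config.library_size_mean / 1e9,
    )
    all_rates = np.concatenate([base_rate, filler_rate])
    all_ids = genes + filler_ids
    all_lengths = pd.concat(
        [
            lengths,
            pd.Series(float(config.filler_length), index=filler_ids),
        ]
    )

    # shared-program genes (first cancer type) and TF-program targets
    program_genes = rng.choice(n, size=int(round(config.program_gene_frac * n)), replace=False)
    tf_a_driver = gene_pos[annotation.tf_genes["TF_A"]]
    target_pool = np.flatnonzero(
        ((planted["role"] == "none") & (planted["prc2"] == "pos")).to_numpy()
    )
    tf_targets_idx = rng.choice(
        target_pool, size=min(config.n_tf_targets, len(target_pool)), replace=False
    )
    truth.tf_targets["TF_A"] = [genes[i] for i in tf_targets_idx]

    probe_ids = annotation.probe_manifest["probe_id"].tolist()
    # map gene -> probe row indices (probes were emitted in gene order)
    probes_per_gene: dict[str, list[int]] = {g: [] for g in genes}
    # reconstruct probe->gene by coordinate proximity to the gene anchor
    anchors = meta["anchor"]
    probe_chrom = annotation.probe_manifest["chrom"].to_numpy()
    probe_pos = annotation.probe_manifest["position"].to_numpy() - 1
    for g in genes:
        a = int(anchors[g])
        c = meta.at[g, "chrom"]
        in_range = (probe_chrom == c) & (probe_pos >= a - 40) & (probe_pos <= a + 2100)
        probes_per_gene[g] = list(np.flatnonzero(in_range))
    # anchor spacing (8 kb on each chromosome) guarantees unique assignment

    a_u, b_u = config.beta_unmeth
    a_m, b_m = config.beta_meth
    alpha = config.nb_dispersion
    nb_size = 1.0 / alpha

    cohorts: dict[str, CohortBundle] = {}
    for t_idx, ct in enumerate(types):
        n_s = config.n_normal + config.n_tumor
        sample_ids = [f"{ct}_N{i + 1:02d}" for i in range(config.n_normal)] + [
            f"{ct}_T{i + 1:02d}" for i in range(config.n_tumor)
        ]
        condition = ["normal"] * config.n_normal + ["tumor"] * config.n_tumor
        is_tumor = np.array([c == "tumor" for c in condition])

        lib_factor = np.exp(rng.normal(0.0, 0.2, size=n_s))
        mu = np.outer(all_rates, lib_factor)  # (genes + fillers) x samples

        # planted expression effects in this cancer type's tumours
        fc = np.ones(n)
        role = planted["role"].to_numpy()
        ta = planted["type_a"].to_numpy()
        tb = planted["type_b"].to_numpy()
        fc[(role == "up_prc2") & (ta == t_idx)] = config.fc_up_prc2
        fc[(role == "plastic") & (ta == t_idx)] = config.fc_up_prc2
        fc[(role == "up_prc2neg") & (ta == t_idx)] = config.fc_up_prc2neg
        fc[(role == "hyper_prc2") & (ta == t_idx)] = config.hyper_downreg
        fc[(role == "plastic") & (tb == t_idx)] = config.hyper_downreg
        fc = np.concatenate([fc, np.ones(config.n_filler_genes)])
        mu[:, is_tumor] *= fc[:, None]

        if t_idx == 0:
            # correlated expression program across tumours of the first type
            z = rng.normal(0.0, config.program_sd, size=config.n_tumor)
            mu[np.ix_(program_genes, np.flatnonzero(is_tumor))] *= np.exp(z)[None, :]
            # TF-coupling program: driver and its targets co-vary
            zt = rng.normal(0.0, config.tf_latent_sd, size=config.n_tumor)
            mu[tf_a_driver, is_tumor] *= np.exp(zt)
            mu[np.ix_(tf_targets_idx, np.flatnonzero(is_tumor))] *= np.exp(
                config.tf_coupling * zt
            )[None, :]

        counts = rng.negative_binomial(nb_size, nb_size / (nb_size + mu))
        counts_df = pd.DataFrame(counts, index=all_ids, columns=sample_ids)

        beta = rng.beta(a_u, b_u, size=(len(probe_ids), n_s))
        hyper_here = np.flatnonzero(
            ((role == "hyper_prc2") & (ta == t_idx))
            | ((role == "plastic") & (tb == t_idx))
        )
        tumor_cols = np.flatnonzero(is_tumor)
        for gi in hyper_here:
            meth_tumors = tumor_cols[
                rng.random(config.n_tumor) < config.hyper_penetrance
            ]
            rows = probes_per_gene[genes[gi]]
            if len(rows) and len(meth_tumors):
                beta[np.ix_(rows, meth_tumors)] = rng.beta(
                    a_m, b_m, size=(len(rows), len(meth_tumors))
                )
        beta_df = pd.DataFrame(beta, index=probe_ids, columns=sample_ids)

        samples = pd.DataFrame(
            {"sample_id": sample_ids, "cancer_type": ct, "condition": condition}
        )
        cohorts[ct] = CohortBundle(
            cancer_type=ct,
            counts=counts_df,
            beta=beta_df,
            samples=samples,
            gene_lengths=all_lengths,
        )
    return cohorts, truth


def write_fixture(
    config: SimulationConfig,
    annotation: AnnotationBundle,
    cohorts: dict[str, CohortBundle],
    truth: TruthTable,
    out_dir,
) -> dict:
    """Write the complete file tree and return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    # manifest paths are relative to out_dir (keeps trees relocatable and
    # byte-identical across runs of the same config)
    def _tsv(df: pd.DataFrame, name: str, index: bool = False) -> None:
        df.to_csv(out / name, sep="\t", index=index)
        paths[name] = name

    def _bed(ivs, name: str) -> None:
        write_bed(ivs, out / name)
        paths[name] = name

    _tsv(annotation.tss_table, "tss_table.tsv")
    _tsv(annotation.probe_manifest, "probe_manifest.tsv")
    _bed(annotation.cgi, "cgi.bed")
    _bed(annotation.chrom_states, "chrom_states.bed")
    _bed(annotation.ezh2_peaks, "ezh2_peaks.bed")
    _bed(annotation.suz12_peaks, "suz12_peaks.bed")
    _bed(annotation.lads, "lads.bed")
    _tsv(annotation.enhancer_links, "enhancer_links.tsv")
    for tf, occs in annotation.motif_occurrences.items():
        _bed(occs, f"motifs_{tf}.bed")
    gmt = out / "gene_sets.gmt"
    with open(gmt, "w") as fh:
        for name, members in annotation.gene_sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")
    paths["gene_sets.gmt"] = "gene_sets.gmt"

    lengths = cohorts[annotation.cancer_types[0]].gene_lengths
    _tsv(lengths.rename("length").rename_axis("gene_id").reset_index(), "gene_lengths.tsv")
    all_samples = []
    for ct, bundle in cohorts.items():
        _tsv(bundle.counts.rename_axis("gene_id"), f"counts_{ct}.tsv", index=True)
        _tsv(bundle.beta.rename_axis("probe_id"), f"beta_{ct}.tsv", index=True)
        all_samples.append(bundle.samples)
    _tsv(pd.concat(all_samples, ignore_index=True), "samples.tsv")
    _tsv(truth.labels.rename_axis("gene_id"), "truth_labels.tsv", index=True)
    _tsv(truth.flags.rename_axis("gene_id"), "truth_flags.tsv", index=True)

    manifest = {
        "config_hash": config.hash(),
        "config": asdict(config),
        "files": paths,
        "tf_genes": annotation.tf_genes,
        "cancer_types": annotation.cancer_types,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def simulate_all(config: SimulationConfig):
    """Convenience: annotation + cohorts + truth in one call."""
    annotation = simulate_annotation(config)
    cohorts, truth = simulate_cohort(config, annotation)
    return annotation, cohorts, truth
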