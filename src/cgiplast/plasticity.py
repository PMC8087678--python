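"""Cross-cancer statistics: plastic genes, cancer-type-restricted genes,
PCA distance ratios, and signature/quintile scoring.

A "plastic" gene is upregulated in one cancer type and promoter-
hypermethylated in at least one other, within the same PRC2 class. A
"cancer-type-restricted" gene has tumor expression at least 2-fold higher in
one cancer type than in all other tumors. The PCA distance ratio
(mean inter-cancer-type distance / mean intra-type distance, in the first
principal components of log2(FPKM+1)) quantifies how well a gene class
separates cancer types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .classify import HYPER_PRC2, HYPER_PRC2NEG, UP_PRC2, UP_PRC2NEG
from .diffexpr import nb_two_group_test

EPS_FPKM = 0.01  # pseudo-floor for fold-change ratios


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file (set name, description, members...) into a dict."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    return sets


def cd8_signatures() -> dict[str, list[str]]:
    """The two bundled cytotoxic CD8 T-cell signature gene lists used to
    score immune infiltration against inflammatory-pathway expression."""
    from importlib import resources

    with resources.as_file(
        resources.files("cgiplast") / "data" / "cd8_signatures.gmt"
    ) as p:
        return read_gmt(p)


@dataclass
class PlasticitySummary:
    prc2_class: str  # "PRC2_POS" or "PRC2_NEG"
    per_type: pd.DataFrame  # cancer_type, n_upregulated, n_plastic, pct_plastic
    plastic_genes: list[str] = field(default_factory=list)


def _plastic_for_pair(
    calls: pd.DataFrame, up_label: str, hyper_label: str
) -> tuple[set[str], pd.DataFrame]:
    types = sorted(calls["cancer_type"].unique())
    up_by_type = {
        t: set(calls.loc[(calls["cancer_type"] == t) & (calls["label"] == up_label), "gene_id"])
        for t in types
    }
    hyper_by_type = {
        t: set(
            calls.loc[
                (calls["cancer_type"] == t) & (calls["label"] == hyper_label), "gene_id"
            ]
        )
        for t in types
    }
    plastic: set[str] = set()
    rows = []
    for t in types:
        other_hyper = set().union(
            *(hyper_by_type[o] for o in types if o != t)
        ) if len(types) > 1 else set()
        plastic_t = up_by_type[t] & other_hyper
        plastic |= plastic_t
        n_up = len(up_by_type[t])
        rows.append(
            {
                "cancer_type": t,
                "n_upregulated": n_up,
                "n_plastic": len(plastic_t),
                "pct_plastic": len(plastic_t) / n_up if n_up else np.nan,
            }
        )
    return plastic, pd.DataFrame(rows)


def plastic_genes(class_calls: pd.DataFrame) -> dict[str, PlasticitySummary]:
    """Plastic-gene summaries, computed separately for each PRC2 class.

    ``class_calls`` holds one row per (gene, cancer type) with a ``label``
    column. Requires calls for at least two cancer types.
    """
    if class_calls["cancer_type"].nunique() < 2:
        raise ValueError("plasticity requires class calls for >=2 cancer types")
    out = {}
    for key, up_label, hyper_label in (
        ("PRC2_POS", UP_PRC2, HYPER_PRC2),
        ("PRC2_NEG", UP_PRC2NEG, HYPER_PRC2NEG),
    ):
        plastic, per_type = _plastic_for_pair(class_calls, up_label, hyper_label)
        out[key] = PlasticitySummary(
            prc2_class=key, per_type=per_type, plastic_genes=sorted(plastic)
        )
    return out


def cancer_restricted_genes(
    fpkm: pd.DataFrame,
    tumor_sample_types: pd.Series,
    class_gene_set: Sequence[str],
    target_type: str,
    fc_cutoff: float = 2.0,
    counts: pd.DataFrame | None = None,
    alpha: float = 0.05,
    require_significance: bool = True,
) -> list[str]:
    """Class genes expressed >= fc_cutoff-fold higher in the target type's
    tumors than in all other tumors.

    Fold-change uses mean FPKM with a 0.01 pseudo-floor. When
    ``require_significance`` is set (the default) genes must additionally
    reach BH-adjusted p < ``alpha`` in a one-vs-rest NB test on ``counts``.
    """
    genes = [g for g in class_gene_set if g in fpkm.index]
    if not genes:
        return []
    in_type = list(tumor_sample_types.index[tumor_sample_types == target_type])
    rest = list(tumor_sample_types.index[tumor_sample_types != target_type])
    if len(in_type) < 2 or len(rest) < 2:
        raise ValueError("need >=2 tumors in the target type and in the rest")
    mean_in = fpkm.loc[genes, in_type].mean(axis=1)
    mean_rest = fpkm.loc[genes, rest].mean(axis=1)
    fc = (mean_in + EPS_FPKM) / (mean_rest + EPS_FPKM)
    selected = fc[fc >= fc_cutoff].index
    if require_significance:
        if counts is None:
            raise ValueError("counts are required when require_significance=True")
        # normalization must see the whole transcriptome, not just the class
        de = nb_two_group_test(counts, rest, in_type).loc[genes]
        sig = de.index[(de["padj"] < alpha) & (de["log2fc"] > 0)]
        selected = [g for g in selected if g in set(sig)]
    return sorted(selected)


def pca_distance_ratio(
    fpkm: pd.DataFrame,
    tumor_sample_types: pd.Series,
    gene_set: Sequence[str],
    n_pcs: int = 2,
) -> float:
    """mean(inter-type distance) / mean(intra-type distance) in PCA space.

    PCA is computed on log2(FPKM+1) over ``gene_set``, gene-centered, samples
    projected on the first ``n_pcs`` components. Returns +inf when the
    intra-type distance is exactly zero.
    """
    genes = [g for g in gene_set if g in fpkm.index]
    if len(genes) < n_pcs:
        raise ValueError("gene set smaller than the number of components")
    samples = list(tumor_sample_types.index)
    labels = tumor_sample_types.to_numpy()
    if len(set(labels)) < 2:
        raise ValueError("need >=2 cancer types")
    x = np.log2(fpkm.loc[genes, samples].to_numpy(dtype=float) + 1.0).T
    x = x - x.mean(axis=0, keepdims=True)
    if not np.any(x):
        raise ValueError("degenerate (zero-variance) expression input")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :n_pcs] * s[:n_pcs]
    d = squareform(pdist(coords))
    same = labels[:, None] == labels[None, :]
    triu = np.triu(np.ones_like(same, dtype=bool), k=1)
    intra = d[same & triu]
    inter = d[~same & triu]
    if intra.size == 0 or intra.mean() <= 1e-12 * max(inter.mean(), 1.0):
        return float("inf")
    return float(inter.mean() / intra.mean())


def signature_score(fpkm: pd.DataFrame, gene_list: Sequence[str]) -> pd.Series:
    """Per-sample mean of log2(FPKM+1) over the listed genes."""
    present = [g for g in gene_list if g in fpkm.index]
    if not present:
        raise ValueError("no signature gene present in the matrix")
    if len(present) < len(gene_list):
        import warnings

        warnings.warn(
            f"{len(gene_list) - len(present)} signature genes absent, dropped"
        )
    return np.log2(fpkm.loc[present] + 1.0).mean(axis=0)


def stratified_group_test(
    strat_scores: pd.Series,
    outcome_scores: pd.Series,
    q: float = 0.2,
    one_sided: bool = True,
) -> tuple[float, float]:
    """Welch t-test of an outcome score between top-q and bottom-q strata.

    Samples are stratified by ``strat_scores`` (e.g. the mean expression of
    upregulated PRC2+ genes of a pathway, or a TF's expression with q=0.2
    giving quintiles); the test compares ``outcome_scores`` between the top
    and bottom strata. One-sided p tests top > bottom.
    """
    common = strat_scores.index.intersection(outcome_scores.index)
    s = strat_scores.loc[common].sort_values()
    k = max(int(np.floor(len(s) * q)), 1)
    bottom, top = list(s.index[:k]), list(s.index[-k:])
    if len(top) < 2 or len(bottom) < 2:
        raise ValueError("strata must contain >=2 samples")
    a = outcome_scores.loc[top].to_numpy(dtype=float)
    b = outcome_scores.loc[bottom].to_numpy(dtype=float)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if one_sided:
        p = p / 2 if t > 0 else 1 - p / 2
    return float(t), float(p)


def tf_stratified_target_fc(
    fpkm: pd.DataFrame,
    tf_gene: str,
    target_genes: Sequence[str],
    tumor_ids: Sequence[str] | None = None,
    quantile: float = 0.2,
    fc_cutoff: float = 1.5,
) -> pd.DataFrame:
    """Target fold-changes between TF-high and TF-low tumors.

    Tumors are binned into the upper and lower ``quantile`` of the TF's
    expression; per target, FC = mean(high) / mean(low) with a pseudo-floor,
    categorized up (FC >= cutoff), down (FC <= 1/cutoff) or unchanged.
    """
    if tf_gene not in fpkm.index:
        raise ValueError(f"TF gene {tf_gene!r} absent from the expression matrix")
    cols = list(tumor_ids) if tumor_ids is not None else list(fpkm.columns)
    tf = fpkm.loc[tf_gene, cols].sort_values()
    k = max(int(np.floor(len(tf) * quantile)), 1)
    if k < 2:
        raise ValueError("fewer than 2 samples per quantile bin")
    low_ids, high_ids = list(tf.index[:k]), list(tf.index[-k:])
    present = [g for g in target_genes if g in fpkm.index]
    mean_hi = fpkm.loc[present, high_ids].mean(axis=1)
    mean_lo = fpkm.loc[present, low_ids].mean(axis=1)
    fc = (mean_hi + EPS_FPKM) / (mean_lo + EPS_FPKM)
    category = np.where(
        fc >= fc_cutoff, "up", np.where(fc <= 1 / fc_cutoff, "down", "unchanged")
    )
    return pd.DataFrame({"fc": fc, "category": category}, index=present)
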