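"""Reciprocal foreground/background enrichment statistics.

Three test families cover the enrichment analyses:

* gene-set enrichment between two disjoint upregulated gene classes via a
  binomial test approximated by a z-test (run in both directions, swapping
  foreground and background);
* TF motif enrichment in region sets via a one-sided hypergeometric upper
  tail, gated on the TF's own tumor expression (median FPKM > 10);
* 2x2 peak-overlap association via the exact two-sided Fisher test.

Plus summaries of enhancer-to-gene link tables.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, overlap_any
from .diffexpr import bh_adjust


def binomial_z_enrichment(
    fg_genes: Sequence[str],
    bg_genes: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    p_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Per-set one-sided binomial z enrichment of foreground vs background.

    For each set: k = |fg in set|, n = |fg|, with the null rate estimated from
    the background with a continuity guard, p0 = (|bg in set| + 0.5)/(|bg| + 1);
    z = (k/n - p0) / sqrt(p0 (1 - p0) / n), upper-tail normal p. The test is
    run in both directions (foreground and background swapped). ``enriched``
    filters on the unadjusted p (< p_cutoff); BH-adjusted p is also reported.
    """
    fg, bg = set(fg_genes), set(bg_genes)
    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty")
    if fg & bg:
        raise ValueError("foreground and background must be disjoint")
    rows = []
    for direction, f, b in (("fg_vs_bg", fg, bg), ("bg_vs_fg", bg, fg)):
        for name, members in gene_sets.items():
            members = set(members)
            if not members:
                warnings.warn(f"empty gene set {name!r} skipped")
                continue
            k, n = len(f & members), len(f)
            k_bg, n_bg = len(b & members), len(b)
            p0 = (k_bg + 0.5) / (n_bg + 1.0)
            z = (k / n - p0) / np.sqrt(p0 * (1 - p0) / n)
            p = float(stats.norm.sf(z))
            rows.append(
                {
                    "set_id": name,
                    "direction": direction,
                    "k_fg": k,
                    "n_fg": n,
                    "k_bg": k_bg,
                    "n_bg": n_bg,
                    "statistic": z,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    out["padj"] = np.nan
    for direction in out["direction"].unique():
        mask = out["direction"] == direction
        out.loc[mask, "padj"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    out["enriched"] = out["p"] < p_cutoff
    return out


def hypergeom_region_enrichment(
    fg_regions: Sequence[GenomicInterval],
    bg_regions: Sequence[GenomicInterval],
    motif_occurrences_by_tf: Mapping[str, Sequence[GenomicInterval]],
    tf_median_fpkm: Mapping[str, float],
    fpkm_cutoff: float = 10.0,
    p_cutoff: float = 0.01,
) -> tuple[list[str], pd.DataFrame]:
    """One-sided hypergeometric motif enrichment in foreground regions.

    A region "has" a TF's motif when >=1 predicted occurrence overlaps it.
    With N = |fg| + |bg| regions, K motif-bearing regions, n = |fg| and k
    motif-bearing foreground regions, p = P(X >= k) under
    Hypergeometric(N, K, n). TFs absent from ``tf_median_fpkm`` are excluded
    with a warning; the enriched list requires p < p_cutoff and median tumor
    FPKM > fpkm_cutoff.
    """
    fg, bg = list(fg_regions), list(bg_regions)
    N, n = len(fg) + len(bg), len(fg)
    rows = []
    for tf, occs in motif_occurrences_by_tf.items():
        if tf not in tf_median_fpkm:
            warnings.warn(f"TF {tf!r} absent from expression matrix, excluded")
            continue
        k = int(overlap_any(fg, occs).sum())
        k_bg = int(overlap_any(bg, occs).sum())
        K = k + k_bg
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "tf": tf,
                "k_fg": k,
                "n_fg": n,
                "k_bg": k_bg,
                "n_bg": len(bg),
                "statistic": k,
                "p": p,
                "median_fpkm": float(tf_median_fpkm[tf]),
            }
        )
    columns = [
        "tf", "k_fg", "n_fg", "k_bg", "n_bg", "statistic", "p", "median_fpkm",
        "padj", "enriched",
    ]
    if not rows:
        return [], pd.DataFrame(columns=columns)
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["p"].to_numpy())
    out["enriched"] = (out["p"] < p_cutoff) & (out["median_fpkm"] > fpkm_cutoff)
    return sorted(out.loc[out["enriched"], "tf"]), out


def fisher_overlap_test(table) -> tuple[float, float]:
    """Exact two-sided Fisher test on a 2x2 table.

    Returns (odds_ratio, p). The odds ratio is the sample odds ratio with
    Haldane correction (+0.5 to every cell) when any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("negative cell count")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel()
    if (t == 0).any():
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(a * d / (b * c)), float(p)


def enhancers_per_gene(
    link_table: pd.DataFrame, gene_sets_by_class: Mapping[str, Sequence[str]]
) -> dict[str, float]:
    """Mean number of distinct linked enhancer peaks per gene, per class.

    Genes with no row in the link table contribute 0 links.
    """
    n_links = link_table.groupby("gene_id")["peak_id"].nunique()
    out = {}
    for cls, genes in gene_sets_by_class.items():
        genes = list(genes)
        if not genes:
            out[cls] = float("nan")
            continue
        out[cls] = float(n_links.reindex(genes).fillna(0).mean())
    return out


def linked_regions_for_genes(
    link_table: pd.DataFrame, genes: Sequence[str]
) -> list[GenomicInterval]:
    """Distinct enhancer intervals linked to any of the listed genes."""
    sub = link_table[link_table["gene_id"].isin(set(genes))]
    sub = sub.drop_duplicates(subset="peak_id")
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end), name=r.peak_id)
        for r in sub.itertuples(index=False)
    ]
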