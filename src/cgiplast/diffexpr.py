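"""Expression preprocessing and a self-contained negative-binomial Wald test.

The two-group test follows the standard RNA-Seq recipe: median-of-ratios
size factors, per-gene NB dispersion (var = mu + alpha * mu^2) estimated by
the method of moments within groups, a log2 fold-change from pseudo-counted
normalized group means, a delta-method standard error, a Wald statistic
referred to a t distribution with residual degrees of freedom, and
Benjamini-Hochberg correction restricted to expression-filter-passing genes.
No dispersion shrinkage or independent filtering is applied; an externally
computed DE table with the same columns can be substituted anywhere the
pipeline consumes one.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

LN2 = np.log(2.0)


def compute_fpkm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """FPKM_gs = count_gs * 1e9 / (length_g * total_counts_s)."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"gene lengths missing for {missing} ...")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero library size for samples {bad}")
    return counts * 1e9 / np.outer(lengths.to_numpy(), totals.to_numpy())


def expression_filter(
    counts: pd.DataFrame,
    fpkm: pd.DataFrame,
    normal_ids: Sequence[str],
    tumor_ids: Sequence[str],
    detect_frac: float = 0.8,
    fpkm_cutoff: float = 1.0,
    fpkm_frac: float = 0.5,
) -> pd.Series:
    """Detected-expression filter ahead of differential testing.

    A gene passes iff strictly more than ``detect_frac`` of normal samples AND
    of tumor samples have count > 0, and strictly more than ``fpkm_frac`` of
    tumor samples have FPKM > ``fpkm_cutoff``.
    """
    if len(normal_ids) == 0 or len(tumor_ids) == 0:
        raise ValueError("both sample groups must be non-empty")
    normal_ids, tumor_ids = list(normal_ids), list(tumor_ids)
    det_n = (counts[normal_ids] > 0).mean(axis=1) > detect_frac
    det_t = (counts[tumor_ids] > 0).mean(axis=1) > detect_frac
    expr_t = (fpkm[tumor_ids] > fpkm_cutoff).mean(axis=1) > fpkm_frac
    return det_n & det_t & expr_t


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors.

    The reference is the per-gene geometric mean across samples; genes with a
    zero in any sample are excluded from the reference set. Size factors are
    scaled to median 1 (they are defined only up to a constant; this
    convention makes normalized counts exactly invariant to rescaling a
    single sample's library).
    """
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("sample with all-zero counts")
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has nonzero counts in every sample")
    sub = x[positive]
    ref = np.exp(np.log(sub).mean(axis=1))
    sf = np.median(sub / ref[:, None], axis=0)
    sf = sf / np.median(sf)
    return pd.Series(sf, index=counts.columns)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def nb_two_group_test(
    counts: pd.DataFrame,
    group_a_ids: Sequence[str],
    group_b_ids: Sequence[str],
    passed_filter: pd.Series | None = None,
    dispersion_floor: float = 1e-8,
) -> pd.DataFrame:
    """Per-gene NB Wald test of group B (tumor) vs group A (reference).

    Returns a DataFrame indexed by gene with columns base_mean, log2fc, se,
    p, padj, passed_filter. BH adjustment is computed over filter-passing
    genes only; padj is NaN elsewhere.
    """
    a_ids, b_ids = list(group_a_ids), list(group_b_ids)
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("need >=2 samples per group")
    sub = counts[a_ids + b_ids]
    sf = size_factors(sub)
    q = sub / sf
    qa, qb = q[a_ids].to_numpy(), q[b_ids].to_numpy()
    na, nb = len(a_ids), len(b_ids)

    ma, mb = qa.mean(axis=1), qb.mean(axis=1)
    va, vb = qa.var(axis=1, ddof=1), qb.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = np.where(ma > 0, (va - ma) / ma**2, 0.0)
        alpha_b = np.where(mb > 0, (vb - mb) / mb**2, 0.0)
    alpha = ((na - 1) * alpha_a + (nb - 1) * alpha_b) / (na + nb - 2)
    alpha = np.maximum(alpha, dispersion_floor)

    log2fc = np.log2(mb + 0.5) - np.log2(ma + 0.5)
    var_ma = (ma + alpha * ma**2) / na
    var_mb = (mb + alpha * mb**2) / nb
    se = np.sqrt(var_ma / (ma + 0.5) ** 2 + var_mb / (mb + 0.5) ** 2) / LN2
    se = np.maximum(se, 1e-12)
    z = log2fc / se
    # dispersion is estimated from na+nb-2 residual df; a t reference keeps
    # the test calibrated at small sample sizes where a normal is too light
    p = 2.0 * stats.t.sf(np.abs(z), na + nb - 2)

    if passed_filter is None:
        passed = np.ones(len(sub), dtype=bool)
    else:
        passed = passed_filter.reindex(sub.index).fillna(False).to_numpy(dtype=bool)
    padj = np.full(len(sub), np.nan)
    if passed.any():
        padj[passed] = bh_adjust(p[passed])

    return pd.DataFrame(
        {
            "base_mean": q.mean(axis=1).to_numpy(),
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "padj": padj,
            "passed_filter": passed,
        },
        index=sub.index,
    )
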