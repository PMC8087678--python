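"""Per-cancer-type class calls: hypermethylated and upregulated CGI genes.

The decision rules, applied independently per cancer type:

* a promoter is hypermethylated when beta < 0.2 in strictly more than 90% of
  nonmalignant samples AND beta > 0.3 in strictly more than 15% of tumors;
* a gene is upregulated when it passes the expression filter with adjusted
  p < 0.05 and log2 fold-change (tumor vs nonmalignant) > 1;
* hypermethylated gene classes additionally require the absence of
  significant upregulation (log2fc < 1 OR adjusted p > 0.05), which makes
  the HYPER and UP labels mutually exclusive by construction.

Gene classes are keyed on disjoint PRC2 gene sets: PRC2+ genes (at least one
PRC2-positive promoter, passing the normal-expression gate) and PRC2- genes
(all promoters PRC2-negative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .promoters import PRC2_NEG, PRC2_POS, Promoter

HYPER_PRC2 = "HYPER_PRC2"
UP_PRC2 = "UP_PRC2"
UP_PRC2NEG = "UP_PRC2NEG"
HYPER_PRC2NEG = "HYPER_PRC2NEG"
NONE = "NONE"

LABELS = (HYPER_PRC2, UP_PRC2, UP_PRC2NEG, HYPER_PRC2NEG, NONE)


def call_hypermethylated_promoters(
    promoter_beta: pd.DataFrame,
    normal_ids: Sequence[str],
    tumor_ids: Sequence[str],
    low: float = 0.2,
    low_frac: float = 0.9,
    high: float = 0.3,
    high_frac: float = 0.15,
) -> pd.Series:
    """Boolean hypermethylation flag per promoter (NaN when undecidable).

    Missing beta values are excluded from both numerator and denominator;
    a promoter whose normal samples are all missing gets a missing call.
    """
    if len(normal_ids) == 0 or len(tumor_ids) == 0:
        raise ValueError("both sample groups must be non-empty")
    bn = promoter_beta[list(normal_ids)]
    bt = promoter_beta[list(tumor_ids)]
    n_norm = bn.notna().sum(axis=1)
    n_tum = bt.notna().sum(axis=1)
    frac_low = (bn < low).sum(axis=1) / n_norm
    frac_high = (bt > high).sum(axis=1) / n_tum.replace(0, np.nan)
    call = (frac_low > low_frac) & (frac_high > high_frac)
    call = call.astype("object")
    call[(n_norm == 0) | (n_tum == 0)] = np.nan
    return call


def call_upregulated_genes(
    de_results: pd.DataFrame,
    padj_cutoff: float = 0.05,
    lfc_cutoff: float = 1.0,
) -> pd.Series:
    """Upregulation flag: passed_filter AND padj < cutoff AND log2fc > cutoff.

    The tumor-expression floor (FPKM > 1, or > 4 in the robustness re-run) is
    part of the expression filter already recorded in ``passed_filter``.
    """
    return (
        de_results["passed_filter"]
        & (de_results["padj"] < padj_cutoff)
        & (de_results["log2fc"] > lfc_cutoff)
    )


@dataclass
class ClassThresholds:
    beta_low: float = 0.2
    beta_low_frac: float = 0.9
    beta_high: float = 0.3
    beta_high_frac: float = 0.15
    padj_cutoff: float = 0.05
    lfc_cutoff: float = 1.0


def assemble_gene_classes(
    hyper_flags: pd.Series,
    de_results: pd.DataFrame,
    promoters: Sequence[Promoter],
    prc2_pos_gated_genes: Iterable[str],
    cancer_type: str,
    thresholds: ClassThresholds | None = None,
) -> pd.DataFrame:
    """Assign each gene one label for this cancer type.

    ``hyper_flags`` is the per-promoter hypermethylation call,
    ``prc2_pos_gated_genes`` the PRC2+ genes passing the normal-expression
    gate. Genes absent from the DE table count as not significantly
    upregulated (they were not testable), which matches the decision tree:
    the hyper branch only excludes genes with demonstrated upregulation.
    """
    th = thresholds or ClassThresholds()
    gated = set(prc2_pos_gated_genes)

    prom_status: dict[str, list[Promoter]] = {}
    for p in promoters:
        for g in p.gene_ids:
            prom_status.setdefault(g, []).append(p)

    up = call_upregulated_genes(de_results, th.padj_cutoff, th.lfc_cutoff)

    rows = []
    for gene, proms in prom_status.items():
        statuses = {p.prc2_status for p in proms}
        is_pos_gene = PRC2_POS in statuses and gene in gated
        is_neg_gene = statuses == {PRC2_NEG}
        if gene in de_results.index:
            de = de_results.loc[gene]
            lfc, padj = float(de["log2fc"]), float(de["padj"])
            is_up = bool(up.get(gene, False))
            # absence of significant upregulation (NaN padj = untested = not up)
            not_up = (lfc < th.lfc_cutoff) or (np.isnan(padj) or padj > th.padj_cutoff)
        else:
            lfc, padj = np.nan, np.nan
            is_up, not_up = False, True

        def _flag(pid: str) -> bool:
            v = hyper_flags.get(pid, False)
            return bool(v) if v == v else False  # NaN-safe truthiness

        def _hyper(status: str) -> list[str]:
            return [
                p.promoter_id
                for p in proms
                if p.prc2_status == status and _flag(p.promoter_id)
            ]

        label = NONE
        hyper_proms: list[str] = []
        if is_pos_gene:
            hyper_proms = _hyper(PRC2_POS)
            if is_up:
                label = UP_PRC2
            elif hyper_proms and not_up:
                label = HYPER_PRC2
        elif is_neg_gene:
            hyper_proms = _hyper(PRC2_NEG)
            if is_up:
                label = UP_PRC2NEG
            elif hyper_proms and not_up:
                label = HYPER_PRC2NEG

        rows.append(
            {
                "gene_id": gene,
                "cancer_type": cancer_type,
                "label": label,
                "n_promoters": len(proms),
                "n_hyper_promoters": len(hyper_proms),
                "hyper_promoter_ids": ",".join(hyper_proms),
                "log2fc": lfc,
                "padj": padj,
            }
        )
    out = pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)
    return out
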