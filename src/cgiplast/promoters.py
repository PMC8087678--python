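"""Curation of CGI promoters: windowing, probe mapping, merging, beta averaging.

The curated unit of analysis is a promoter window around one or more TSSs
that (i) contains at least one methylation probe, (ii) does not sit on chrY
or chrM, and (iii) overlaps a CpG island. Neighbouring windows covered by an
identical probe set are merged into a single promoter, since their averaged
methylation would be indistinguishable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, overlap_any, promoter_window

PRC2_POS = "PRC2_POS"
PRC2_NEG = "PRC2_NEG"
AMBIGUOUS = "AMBIGUOUS"
UNSET = "UNSET"


@dataclass(frozen=True)
class Promoter:
    promoter_id: str
    interval: GenomicInterval
    tss_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    probe_ids: tuple[str, ...]
    is_cgi: bool = True
    prc2_status: str = UNSET

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise ValueError("promoters must carry at least one probe")


def curate_promoters(
    tss_table: pd.DataFrame,
    probe_manifest: pd.DataFrame,
    cgi: Sequence[GenomicInterval],
    excluded_chroms: Iterable[str] = ("chrY", "chrM"),
    upstream: int = 250,
    downstream: int = 500,
) -> list[Promoter]:
    """Window TSSs, assign probes, merge identical probe sets, filter to CGIs.

    ``tss_table`` columns: tss_id, gene_id, chrom, position (1-based), strand.
    ``probe_manifest`` columns: probe_id, chrom, position (1-based, the probed
    CpG coordinate). Probes on chromosomes absent from the TSS table are
    ignored with a warning. Windows containing no probe are dropped, as are
    promoters on excluded chromosomes and those without CGI overlap.
    """
    excluded = set(excluded_chroms)
    tss_chroms = set(tss_table["chrom"])
    unknown = set(probe_manifest["chrom"]) - tss_chroms
    if unknown:
        warnings.warn(
            f"ignoring probes on chromosomes without TSSs: {sorted(unknown)}"
        )
    probes = probe_manifest[probe_manifest["chrom"].isin(tss_chroms)]
    probe_pos = {
        c: (g["position"].to_numpy() - 1, g["probe_id"].to_numpy())
        for c, g in probes.groupby("chrom")
    }

    windows: list[tuple[str, str, GenomicInterval, tuple[str, ...]]] = []
    for row in tss_table.itertuples(index=False):
        win = promoter_window(
            row.chrom, int(row.position) - 1, row.strand, upstream, downstream
        )
        pos, ids = probe_pos.get(row.chrom, (np.array([]), np.array([])))
        inside = (pos >= win.start) & (pos < win.end)
        if not inside.any():
            continue  # promoters with no probe coverage are excluded
        windows.append((row.tss_id, row.gene_id, win, tuple(sorted(ids[inside]))))

    # merge windows sharing an identical probe set
    by_probes: dict[tuple[str, ...], list[tuple[str, str, GenomicInterval]]] = {}
    for tss_id, gene_id, win, pset in windows:
        by_probes.setdefault(pset, []).append((tss_id, gene_id, win))

    promoters: list[Promoter] = []
    for pset, members in sorted(by_probes.items()):
        ivs = [m[2] for m in members]
        chrom = ivs[0].chrom
        if chrom in excluded:
            continue
        merged = GenomicInterval(
            chrom,
            min(iv.start for iv in ivs),
            max(iv.end for iv in ivs),
            ivs[0].strand,
        )
        tss_ids = tuple(sorted({m[0] for m in members}))
        gene_ids = tuple(sorted({m[1] for m in members}))
        promoters.append(
            Promoter(
                promoter_id="",
                interval=merged,
                tss_ids=tss_ids,
                gene_ids=gene_ids,
                probe_ids=pset,
            )
        )

    # keep only promoters overlapping a CpG island
    flags = overlap_any([p.interval for p in promoters], cgi)
    promoters = [p for p, keep in zip(promoters, flags) if keep]
    promoters.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.tss_ids))
    return [
        replace(p, promoter_id=f"P{i:06d}", is_cgi=True)
        for i, p in enumerate(promoters)
    ]


def promoter_beta(
    promoters: Sequence[Promoter], probe_beta: pd.DataFrame
) -> pd.DataFrame:
    """Promoter x sample matrix of mean beta over each promoter's probes.

    Missing probe values are dropped from the per-sample mean; an entry is
    missing only when every probe is missing in that sample.
    """
    rows = []
    for p in promoters:
        present = [pid for pid in p.probe_ids if pid in probe_beta.index]
        if not present:
            raise ValueError(
                f"promoter {p.promoter_id} has no probes in the beta matrix"
            )
        rows.append(probe_beta.loc[present].mean(axis=0, skipna=True))
    return pd.DataFrame(rows, index=[p.promoter_id for p in promoters])


def map_genes(
    promoters: Sequence[Promoter],
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Bidirectional gene <-> promoter index (merged promoters may span genes)."""
    gene_to_prom: dict[str, list[str]] = {}
    prom_to_gene: dict[str, list[str]] = {}
    for p in promoters:
        prom_to_gene[p.promoter_id] = list(p.gene_ids)
        for g in p.gene_ids:
            gene_to_prom.setdefault(g, []).append(p.promoter_id)
    return gene_to_prom, prom_to_gene


def promoters_to_frame(promoters: Sequence[Promoter]) -> pd.DataFrame:
    """Flat table representation (the TSV the pipeline writes)."""
    return pd.DataFrame(
        {
            "promoter_id": [p.promoter_id for p in promoters],
            "chrom": [p.interval.chrom for p in promoters],
            "start": [p.interval.start for p in promoters],
            "end": [p.interval.end for p in promoters],
            "strand": [p.interval.strand for p in promoters],
            "tss_ids": [",".join(p.tss_ids) for p in promoters],
            "gene_ids": [",".join(p.gene_ids) for p in promoters],
            "probe_ids": [",".join(p.probe_ids) for p in promoters],
            "is_cgi": [p.is_cgi for p in promoters],
            "prc2_status": [p.prc2_status for p in promoters],
        }
    )
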