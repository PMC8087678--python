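"""PRC2 occupancy annotation of CGI promoters.

A promoter is PRC2-positive when it overlaps both an H3K27me3-bearing
chromatin state (bivalent/poised TSS, flanking bivalent, or repressed
Polycomb: states 10, 11, 13 of the 15-state model) and a ChIP peak for a
PRC2 core subunit (EZH2 or SUZ12, interchangeable evidence). A promoter
with no such state and no subunit peak is PRC2-negative; anything else is
ambiguous. A gene-level class and a normal-tissue expression gate
(median FPKM < 4 in nonmalignant samples) complete the PRC2+ gene set.
"""

from __future__ import annotations

import re
from dataclasses import replace
from typing import Iterable, Sequence

import pandas as pd

from .intervals import GenomicInterval, overlap_any
from .promoters import AMBIGUOUS, PRC2_NEG, PRC2_POS, Promoter

_STATE_RE = re.compile(r"^(\d+)")


def parse_state_number(label: str) -> int:
    m = _STATE_RE.match(label)
    if not m:
        raise ValueError(f"unparseable chromatin state label: {label!r}")
    return int(m.group(1))


def classify_prc2(
    promoters: Sequence[Promoter],
    segments: Sequence[GenomicInterval],
    ezh2_peaks: Sequence[GenomicInterval],
    suz12_peaks: Sequence[GenomicInterval],
    h3k27me3_states: Iterable[int] = (10, 11, 13),
) -> list[Promoter]:
    """Return promoters with prc2_status set (three-way partition)."""
    wanted = set(h3k27me3_states)
    marked_segments = [s for s in segments if parse_state_number(s.name) in wanted]
    ivs = [p.interval for p in promoters]
    has_state = overlap_any(ivs, marked_segments)
    has_peak = overlap_any(ivs, list(ezh2_peaks) + list(suz12_peaks))
    out = []
    for p, st, pk in zip(promoters, has_state, has_peak):
        if st and pk:
            status = PRC2_POS
        elif not st and not pk:
            status = PRC2_NEG
        else:
            status = AMBIGUOUS
        out.append(replace(p, prc2_status=status))
    return out


def gene_prc2_class(promoters: Sequence[Promoter]) -> dict[str, str]:
    """Gene-level PRC2 class from promoter statuses.

    A gene is PRC2_POS if any of its CGI promoters is PRC2_POS, PRC2_NEG only
    if all of them are PRC2_NEG; genes with only ambiguous or mixed evidence
    belong to neither class and are omitted from the mapping.
    """
    statuses: dict[str, set[str]] = {}
    for p in promoters:
        for g in p.gene_ids:
            statuses.setdefault(g, set()).add(p.prc2_status)
    out = {}
    for g, st in statuses.items():
        if PRC2_POS in st:
            out[g] = PRC2_POS
        elif st == {PRC2_NEG}:
            out[g] = PRC2_NEG
    return out


def normal_expression_gate(
    genes: Iterable[str],
    fpkm: pd.DataFrame,
    normal_sample_ids: Sequence[str],
    cutoff: float = 4.0,
) -> set[str]:
    """Keep genes whose median FPKM over normal samples is strictly below cutoff.

    PRC2-occupied genes are expected to be near-silent in normal tissue; this
    gate removes genes whose ESC-derived annotation does not carry over.
    """
    if len(normal_sample_ids) == 0:
        raise ValueError("normal_expression_gate requires >=1 normal sample")
    genes = [g for g in genes if g in fpkm.index]
    med = fpkm.loc[genes, list(normal_sample_ids)].median(axis=1)
    return set(med.index[med < cutoff])
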