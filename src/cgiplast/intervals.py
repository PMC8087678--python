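"""Genomic interval model, promoter windowing, overlap engine and BED/bedGraph I/O.

All internal coordinates are 0-based half-open, the native BED convention.
Tab-separated annotation tables (TSS tables, probe manifests) carry 1-based
positions and are converted on read by the modules that consume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

VALID_STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Raised when a BED/bedGraph line cannot be parsed."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open, optionally stranded genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff >=1 bp is shared. Strand is ignored."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 records; track/browser/comment lines are skipped.

    Strand defaults to "." when column 6 is absent. Coordinates are taken
    verbatim (BED is already 0-based half-open). Malformed lines raise
    :class:`BedParseError` naming the offending line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand, name))
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write BED6 (score column fixed at 0)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def promoter_window(
    chrom: str,
    tss_position: int,
    strand: str,
    upstream: int = 250,
    downstream: int = 500,
    name: str = "",
) -> GenomicInterval:
    """Strand-relative promoter window around a TSS (0-based TSS coordinate).

    The window spans ``upstream`` bp 5' of the TSS through ``downstream`` bp 3'
    of it and includes the TSS base itself, so the unclipped length is
    ``upstream + downstream + 1``. On the minus strand the window is mirrored.
    The left edge is clipped at position 0.
    """
    if tss_position < 0:
        raise ValueError("tss_position must be >= 0")
    if strand == "+":
        start, end = tss_position - upstream, tss_position + downstream + 1
    elif strand == "-":
        start, end = tss_position - downstream, tss_position + upstream + 1
    else:
        raise ValueError("promoter windows require an oriented strand (+ or -)")
    return GenomicInterval(chrom, max(start, 0), end, strand, name)


def _subject_index(subjects: Sequence[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome merged (starts, ends) arrays for fast any-overlap queries."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in subjects:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    index = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        merged: list[list[int]] = []
        for s, e in pairs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.asarray(merged, dtype=np.int64)
        index[chrom] = (arr[:, 0], arr[:, 1])
    return index


def overlap_any(
    queries: Sequence[GenomicInterval], subjects: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean flag per query: shares >=1 bp with any subject (strand ignored)."""
    index = _subject_index(subjects)
    flags = np.zeros(len(queries), dtype=bool)
    for i, q in enumerate(queries):
        entry = index.get(q.chrom)
        if entry is None:
            continue
        starts, ends = entry
        # candidate = rightmost merged block starting before q.end
        j = int(np.searchsorted(starts, q.end, side="left")) - 1
        flags[i] = j >= 0 and ends[j] > q.start
    return flags


def fraction_overlapping(
    queries: Sequence[GenomicInterval], subjects: Sequence[GenomicInterval]
) -> float:
    """count(overlap_any) / len(queries)."""
    if len(queries) == 0:
        raise ValueError("fraction_overlapping requires a non-empty query set")
    return float(np.mean(overlap_any(queries, subjects)))


@dataclass
class SignalTrack:
    """Piecewise-constant signal over one genome (bedGraph semantics).

    Within each chromosome the covered intervals are sorted and
    non-overlapping; uncovered bases read as signal 0.
    """

    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )  # chrom -> (starts, ends, values)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if not 0 <= start < end:
                raise ValueError(f"invalid track interval [{start}, {end})")
            by_chrom.setdefault(chrom, []).append((start, end, value))
        data = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.asarray([r[0] for r in rows], dtype=np.int64)
            ends = np.asarray([r[1] for r in rows], dtype=np.int64)
            values = np.asarray([r[2] for r in rows], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping track intervals on {chrom}")
            data[chrom] = (starts, ends, values)
        return cls(data)


def read_bedgraph(path) -> SignalTrack:
    """Read a bedGraph file into a :class:`SignalTrack`."""
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"line {lineno}: bedGraph needs 4 columns")
            try:
                records.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
    return SignalTrack.from_records(records)


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            starts, ends, values = track.data[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def mean_signal_in_window(track: SignalTrack, interval: GenomicInterval) -> float:
    """Length-weighted mean signal over the interval; uncovered bases count as 0."""
    entry = track.data.get(interval.chrom)
    length = len(interval)
    if entry is None:
        return 0.0
    starts, ends, values = entry
    lo = np.maximum(starts, interval.start)
    hi = np.minimum(ends, interval.end)
    covered = np.clip(hi - lo, 0, None)
    return float(np.dot(covered, values) / length)
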