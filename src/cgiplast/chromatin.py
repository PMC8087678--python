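"""Class-level chromatin summaries: LAD fractions, TSS-centered signal
profiles with moving-window trends, and feature-class correlations."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, SignalTrack, fraction_overlapping, mean_signal_in_window


def lad_fraction_by_class(
    promoters_by_class: Mapping[str, Sequence[GenomicInterval]],
    lads: Sequence[GenomicInterval],
) -> dict[str, float]:
    """Fraction of each class's promoters overlapping a LAD (NaN if empty)."""
    out = {}
    for cls, ivs in promoters_by_class.items():
        if len(ivs) == 0:
            warnings.warn(f"class {cls!r} is empty; LAD fraction missing")
            out[cls] = float("nan")
        else:
            out[cls] = fraction_overlapping(list(ivs), lads)
    return out


@dataclass
class ProfileMatrix:
    """Per-site binned signal around TSSs, strand-oriented (5'->3')."""

    values: np.ndarray  # sites x bins
    bin_starts: np.ndarray  # bin offsets relative to TSS, 5' negative
    flank_bp: int
    bin_bp: int

    @property
    def mean_curve(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def site_means(self) -> np.ndarray:
        return self.values.mean(axis=1)


def tss_signal_profile(
    track: SignalTrack,
    sites: Sequence[tuple[str, int, str]],
    flank_bp: int = 2000,
    bin_bp: int = 100,
) -> ProfileMatrix:
    """Binned mean signal in a strand-oriented window of +/- flank around TSSs.

    ``sites`` are (chrom, tss_position, strand) triples, 0-based TSS. Bins
    tile [-flank, +flank) in 5'->3' orientation: minus-strand profiles are
    mirrored so that upstream is always on the left.
    """
    if flank_bp % bin_bp != 0:
        raise ValueError("flank_bp must be divisible by bin_bp")
    n_bins = 2 * flank_bp // bin_bp
    offsets = np.arange(-flank_bp, flank_bp, bin_bp)
    values = np.zeros((len(sites), n_bins))
    for i, (chrom, tss, strand) in enumerate(sites):
        for j, off in enumerate(offsets):
            if strand == "-":
                # mirror: bin j covers genomic [tss - off - bin, tss - off)
                start = tss - off - bin_bp
            else:
                start = tss + off
            end = start + bin_bp
            if end <= 0:
                continue
            iv = GenomicInterval(chrom, max(start, 0), end)
            # clipped bins are averaged over the full bin width (zero-fill)
            values[i, j] = mean_signal_in_window(track, iv) * len(iv) / bin_bp
    return ProfileMatrix(values=values, bin_starts=offsets, flank_bp=flank_bp, bin_bp=bin_bp)


def moving_window_trend(values: Sequence[float], window: int = 100) -> np.ndarray:
    """Centered rolling mean with edge shrinkage (partial windows at edges)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(np.asarray(values, dtype=float))
    if window > len(s):
        raise ValueError("window larger than the vector")
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def feature_class_correlation(
    class_membership: Sequence[bool], features: pd.DataFrame
) -> pd.Series:
    """Pearson r between 0/1 class membership and each feature column."""
    y = np.asarray(class_membership, dtype=float)
    if len(y) < 3:
        raise ValueError("need >=3 promoters")
    if y.std() == 0:
        raise ValueError("class membership is constant")
    out = {}
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            warnings.warn(f"zero-variance feature {col!r}; correlation missing")
            out[col] = float("nan")
            continue
        out[col] = float(np.corrcoef(y, x)[0, 1])
    return pd.Series(out)
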