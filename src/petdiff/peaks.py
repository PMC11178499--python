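"""Poisson differential test on peak read counts, plus peak annotation.

Replicate-averaged counts are depth-normalized to 30 million total reads
per sample, and each peak is tested one-sided: the higher normalized mean
is referred to the upper tail of a Poisson distribution whose rate is the
lower mean (floored at 1). A peak is condition-selective when p < 1e-5
and the (+1 pseudo-counted) fold change is >= 2; everything else is
shared. Peaks are annotated as promoters when their midpoint lies within
2 kb of a transcription start site, otherwise as enhancers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalize_to_depth",
    "poisson_diff_test",
    "classify_peaks",
    "annotate_promoter_enhancer",
    "quantify_signal_in_bins",
]

DEFAULT_TARGET_DEPTH = 30_000_000


def normalize_to_depth(count, sample_total, target: float = DEFAULT_TARGET_DEPTH):
    """Scale a raw count to a nominal total depth: count * target / sample_total."""
    sample_total = np.asarray(sample_total, dtype=float)
    if np.any(sample_total <= 0):
        raise ValueError("sample_total must be positive")
    return np.asarray(count, dtype=float) * target / sample_total


def poisson_diff_test(mean_norm_a, mean_norm_b):
    """One-sided Poisson enrichment test between two normalized mean counts.

    Vectorized. For each peak: hi = max(a, b), lo = min(a, b); the rate is
    lambda = max(lo, 1); p = P(K >= round(hi) | lambda); fold change is
    (hi + 1) / (lo + 1). Returns (p, fc, direction) where direction is
    "condition1"/"condition2" for whichever mean is higher and "none" for
    ties (including the both-zero case, which yields p = 1, fc = 1).
    """
    a = np.atleast_1d(np.asarray(mean_norm_a, dtype=float))
    b = np.atleast_1d(np.asarray(mean_norm_b, dtype=float))
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("normalized means must be >= 0")
    hi = np.maximum(a, b)
    lo = np.minimum(a, b)
    lam = np.maximum(lo, 1.0)
    k = np.rint(hi)
    # sf(k-1) = P(K >= k)
    p = stats.poisson.sf(k - 1, lam)
    p = np.where((a == 0) & (b == 0), 1.0, p)
    fc = (hi + 1.0) / (lo + 1.0)
    direction = np.where(a > b, "condition1", np.where(b > a, "condition2", "none"))
    if np.isscalar(mean_norm_a) and np.isscalar(mean_norm_b):
        return float(p[0]), float(fc[0]), str(direction[0])
    return p, fc, direction


def classify_peaks(
    mean_norm_a,
    mean_norm_b,
    p_cut: float = 1e-5,
    fc_cut: float = 2.0,
) -> pd.DataFrame:
    """Run the Poisson test per peak and classify selectivity.

    A peak is condition1-/condition2-selective iff p < ``p_cut`` AND
    fc >= ``fc_cut``; otherwise shared. The three class counts always sum
    to the number of peaks.
    """
    p, fc, direction = poisson_diff_test(mean_norm_a, mean_norm_b)
    p = np.atleast_1d(p)
    fc = np.atleast_1d(fc)
    direction = np.atleast_1d(direction)
    selective = (p < p_cut) & (fc >= fc_cut) & (direction != "none")
    cls = np.where(
        selective,
        np.char.add(direction.astype(str), "-selective"),
        "shared",
    )
    return pd.DataFrame(
        {
            "norm_mean_cond1": np.atleast_1d(np.asarray(mean_norm_a, float)),
            "norm_mean_cond2": np.atleast_1d(np.asarray(mean_norm_b, float)),
            "pvalue": p,
            "fold_change": fc,
            "class": cls,
        }
    )


def annotate_promoter_enhancer(peak_midpoints, tss_positions, radius: int = 2000) -> np.ndarray:
    """Label peaks "promoter" when within ``radius`` bp of the nearest TSS.

    The boundary is inclusive: a midpoint exactly ``radius`` away is a
    promoter. Positions are on one chromosome; run per chromosome.
    """
    tss = np.sort(np.asarray(tss_positions, dtype=np.int64))
    if len(tss) == 0:
        raise ValueError("TSS list must be non-empty")
    mid = np.atleast_1d(np.asarray(peak_midpoints, dtype=np.int64))
    i = np.searchsorted(tss, mid)
    left = np.abs(mid - tss[np.clip(i - 1, 0, len(tss) - 1)])
    right = np.abs(tss[np.clip(i, 0, len(tss) - 1)] - mid)
    dist = np.minimum(left, right)
    return np.where(dist <= radius, "promoter", "enhancer")


def quantify_signal_in_bins(read_intervals: pd.DataFrame, bins: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million of read midpoints in genomic bins/intervals.

    ``read_intervals`` and ``bins`` are BED-like frames (chrom, start, end).
    A read is assigned to the interval containing its midpoint; intervals
    must be non-overlapping per chromosome. CPM is relative to the total
    number of reads (assigned or not).
    """
    total = len(read_intervals)
    if total == 0:
        raise ValueError("zero total reads")
    counts = np.zeros(len(bins), dtype=np.int64)
    bins = bins.reset_index(drop=True)
    for chrom, sub in bins.groupby("chrom", sort=False):
        order = np.argsort(sub["start"].to_numpy())
        idx = sub.index.to_numpy()[order]
        starts = sub["start"].to_numpy()[order]
        ends = sub["end"].to_numpy()[order]
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"bins overlap on {chrom}")
        reads = read_intervals[read_intervals["chrom"] == chrom]
        if len(reads) == 0:
            continue
        mids = ((reads["start"].to_numpy() + reads["end"].to_numpy()) // 2).astype(np.int64)
        j = np.searchsorted(starts, mids, side="right") - 1
        jc = np.clip(j, 0, None)
        inside = (j >= 0) & (mids < ends[jc])
        counts += np.bincount(idx[jc[inside]], minlength=len(bins))
    out = bins.copy()
    out["count"] = counts
    out["cpm"] = counts * 1e6 / total
    return out
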