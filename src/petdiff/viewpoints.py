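"""HiChIP viewpoint enrichment scores from a 1-kb contact matrix.

Each viewpoint (an H3K27ac-like peak midpoint) is scored against a
+/-100-kb background window: anchored(b) is the total contact count
between bin b and the window, and the enrichment score is the
viewpoint bin's anchored count divided by the window-mean anchored
count, so ES ~ 1 means no enrichment over the local background. The
double-log10 transform is a display-only compression of the window
heatmap and never feeds statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import BinnedMatrix

__all__ = [
    "Viewpoint",
    "ViewpointESRecord",
    "viewpoint_es",
    "es_by_category",
    "viewpoint_display_transform",
]


@dataclass(frozen=True)
class Viewpoint:
    id: str
    chrom: str
    position: int  # peak summit or midpoint, bp
    category: str = ""


@dataclass
class ViewpointESRecord:
    viewpoint: Viewpoint
    sample_id: str
    es: float  # NaN when undefined
    anchored: np.ndarray  # per-bin anchored counts over the window (<= 201 bins)
    window_bins: tuple  # (first bin, last bin + 1)
    truncated: bool  # window clipped at a chromosome edge
    undefined: bool  # window-mean anchored count was 0


def viewpoint_es(
    matrix1kb: BinnedMatrix, vp: Viewpoint, window_bp: int = 100_000
) -> ViewpointESRecord:
    """Enrichment score of one viewpoint against its +/-``window_bp`` background.

    With W the set of bins within the window of the viewpoint bin v
    (v included), anchored(b) = sum over b' in W of M[b, b'], and
    ES = anchored(v) / mean over W of anchored. A window mean of zero
    leaves the score undefined (NaN, flagged).
    """
    bs = matrix1kb.bin_size
    n = matrix1kb.n_bins
    v = vp.position // bs
    if not 0 <= v < n:
        raise ValueError(f"viewpoint bin {v} outside matrix with {n} bins")
    half = window_bp // bs
    lo = max(0, v - half)
    hi = min(n, v + half + 1)
    truncated = (lo != v - half) or (hi != v + half + 1)
    sub = matrix1kb.matrix[lo:hi, lo:hi]
    anchored = np.asarray(sub.sum(axis=1)).ravel().astype(float)
    mean = anchored.mean()
    undefined = mean == 0
    es = float("nan") if undefined else float(anchored[v - lo] / mean)
    return ViewpointESRecord(vp, "", es, anchored, (lo, hi), truncated, undefined)


def es_by_category(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-viewpoint ES records by category.

    ``records`` needs columns viewpoint_id, category, sample_id, condition,
    es. Returns (mean ES per category x sample, per-viewpoint paired
    differences of condition means: condition2 - condition1). Empty
    categories are dropped with a warning.
    """
    required = {"viewpoint_id", "category", "sample_id", "condition", "es"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    usable = records.dropna(subset=["es"])
    empty = set(records["category"].unique()) - set(usable["category"].unique())
    if empty:
        warnings.warn(f"categories with no defined ES dropped: {sorted(empty)}")
    means = usable.groupby(["category", "sample_id"])["es"].mean().unstack("sample_id")
    cond_means = (
        usable.groupby(["viewpoint_id", "category", "condition"])["es"].mean().unstack("condition")
    )
    conds = sorted(c for c in cond_means.columns)
    if len(conds) >= 2:
        diffs = (cond_means[conds[1]] - cond_means[conds[0]]).rename("es_diff").reset_index()
    else:
        diffs = pd.DataFrame(columns=["viewpoint_id", "category", "es_diff"])
    return means, diffs


def viewpoint_display_transform(window: np.ndarray) -> np.ndarray:
    """Two rounds of log10(1 + x) for heatmap display: monotone, 0 -> 0."""
    window = np.asarray(window, dtype=float)
    if np.any(window < 0):
        raise ValueError("display transform requires non-negative input")
    return np.log10(1.0 + np.log10(1.0 + window))
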