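"""A/B compartment eigenvector (PC1) from a binned cis contact matrix.

The per-sample compartment track is the first principal component of the
Pearson correlation matrix of the observed/expected (O/E) contact map,
computed per chromosome at 100-kb resolution by default. PC1 is defined
only up to sign; :func:`orient_pc1` fixes the sign against a per-bin
covariate so that compartment A comes out positive, and all samples are
oriented against the same reference (never against each other).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .contacts import BinnedMatrix

__all__ = ["CompartmentTrack", "observed_over_expected", "compute_pc1", "orient_pc1"]


@dataclass
class CompartmentTrack:
    """Per-bin PC1 values for one sample; invalid bins are NaN."""

    chrom: str
    bin_size: int
    values: np.ndarray  # NaN at masked bins; unit Euclidean norm over valid bins
    sample_id: str
    oriented: bool = False
    ambiguous_orientation: bool = False

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    def to_bedgraph(self, path) -> None:
        v = self.valid
        starts = np.arange(len(self.values))[v] * self.bin_size
        pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": starts,
                "end": starts + self.bin_size,
                "value": [format(x, ".17g") for x in self.values[v]],
            }
        ).to_csv(path, sep="\t", header=False, index=False)


def observed_over_expected(m: BinnedMatrix) -> np.ndarray:
    """Distance-normalize a raw cis matrix: O/E[i,j] = M[i,j] / expected(|i-j|).

    The expected value at offset d is the mean of M over bin pairs at that
    offset whose two bins both have nonzero coverage. Zero-coverage
    rows/columns and diagonals with zero expected value come back as NaN.
    """
    if m.normalized:
        raise ValueError("observed_over_expected expects a raw matrix")
    a = m.toarray().astype(float)
    n = a.shape[0]
    if n < 10:
        raise ValueError("matrix must have at least 10 bins")
    coverage = a.sum(axis=1)
    valid = coverage > 0
    oe = np.full_like(a, np.nan)
    idx = np.where(valid)[0]
    sub = a[np.ix_(idx, idx)]
    k = len(idx)
    offs = np.abs(idx[:, None] - idx[None, :])
    expected = np.zeros(n)
    counts = np.bincount(offs.ravel(), minlength=n)
    sums = np.bincount(offs.ravel(), weights=sub.ravel(), minlength=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = sums / counts
    exp_mat = expected[offs]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(exp_mat > 0, sub / exp_mat, np.nan)
    oe[np.ix_(idx, idx)] = ratio
    return oe


def compute_pc1(
    oe: np.ndarray, chrom: str = "chr", bin_size: int = 100_000, sample_id: str = "sample"
) -> CompartmentTrack:
    """PC1 of the Pearson correlation matrix of O/E columns.

    Bins whose O/E column is entirely missing or constant cannot enter the
    correlation matrix and are masked. The returned eigenvector has unit
    norm over valid bins; its global sign is arbitrary until oriented.
    """
    oe = np.asarray(oe, dtype=float)
    n = oe.shape[0]
    col_valid = np.zeros(n, dtype=bool)
    with np.errstate(invalid="ignore"):
        for j in range(n):
            col = oe[:, j]
            finite = col[np.isfinite(col)]
            col_valid[j] = len(finite) >= 2 and np.nanstd(finite) > 0
    if col_valid.sum() < 10:
        raise ValueError("fewer than 10 valid bins; PC1 not computable")
    idx = np.where(col_valid)[0]
    corr = pd.DataFrame(oe[np.ix_(idx, idx)]).corr().to_numpy()
    bad = ~np.isfinite(corr).all(axis=0)
    if bad.any():
        idx = idx[~bad]
        if len(idx) < 10:
            raise ValueError("fewer than 10 valid bins after dropping degenerate columns")
        corr = pd.DataFrame(oe[np.ix_(idx, idx)]).corr().to_numpy()
    eigvals, eigvecs = np.linalg.eigh(corr)
    pc1 = eigvecs[:, -1]  # eigh sorts ascending; unit norm by construction
    values = np.full(n, np.nan)
    values[idx] = pc1
    return CompartmentTrack(chrom, bin_size, values, sample_id)


def orient_pc1(
    track: CompartmentTrack, reference: np.ndarray, ambiguity_threshold: float = 0.1
) -> CompartmentTrack:
    """Fix the PC1 sign so it correlates positively with ``reference``.

    ``reference`` is a per-bin covariate that is high in compartment A
    (ground-truth A labels in synthetic mode; e.g. gene density for real
    data); NaN entries are ignored. A correlation magnitude below
    ``ambiguity_threshold`` leaves the sign unchanged but flags the track.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != track.values.shape:
        raise ValueError("reference must match track length")
    both = track.valid & np.isfinite(reference)
    if both.sum() < 0.5 * track.valid.sum():
        raise ValueError("reference must be defined on >= 50% of valid bins")
    if np.std(reference[both]) == 0:
        raise ValueError("reference is constant; cannot orient")
    r = np.corrcoef(track.values[both], reference[both])[0, 1]
    values = -track.values if r < 0 else track.values.copy()
    return replace(
        track,
        values=values,
        oriented=True,
        ambiguous_orientation=bool(abs(r) < ambiguity_threshold),
    )
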