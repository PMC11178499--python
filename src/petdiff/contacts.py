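"""Paired-end-tag (PET) contact data model and core matrix operations.

A PET is one proximity-ligation contact: a pair of genomic positions
(0-based, point coordinates). This module holds the PET container, text
I/O (4-column pairs and 6-column BEDPE), binning into symmetric sparse
contact matrices, vanilla-coverage square-root (VC_SQRT) normalization,
equal down-sampling across samples, and the contact-distance density
decomposition into distance bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "PETSet",
    "GenomeBins",
    "BinnedMatrix",
    "DistanceDensity",
    "read_pairs",
    "write_pairs",
    "bin_pets",
    "vc_sqrt_normalize",
    "downsample_pets",
    "combine_petsets",
    "distance_density",
]


@dataclass
class PETSet:
    """A collection of PETs for one sample.

    Coordinates are stored canonically: (chrom1, pos1) <= (chrom2, pos2)
    lexicographically, enforced at construction.
    """

    sample_id: str
    chrom1: np.ndarray
    pos1: np.ndarray
    chrom2: np.ndarray
    pos2: np.ndarray

    def __post_init__(self) -> None:
        self.chrom1 = np.asarray(self.chrom1, dtype=object)
        self.chrom2 = np.asarray(self.chrom2, dtype=object)
        self.pos1 = np.asarray(self.pos1, dtype=np.int64)
        self.pos2 = np.asarray(self.pos2, dtype=np.int64)
        n = len(self.pos1)
        if not (len(self.chrom1) == len(self.chrom2) == len(self.pos2) == n):
            raise ValueError("PETSet arrays must have equal length")
        # canonical order: swap ends where (chrom2,pos2) < (chrom1,pos1)
        c1 = self.chrom1.astype(str)
        c2 = self.chrom2.astype(str)
        swap = (c2 < c1) | ((c1 == c2) & (self.pos2 < self.pos1))
        if swap.any():
            p1, p2 = self.pos1.copy(), self.pos2.copy()
            self.pos1[swap], self.pos2[swap] = p2[swap], p1[swap]
            ch1, ch2 = self.chrom1.copy(), self.chrom2.copy()
            self.chrom1[swap], self.chrom2[swap] = ch2[swap], ch1[swap]

    def __len__(self) -> int:
        return len(self.pos1)

    @property
    def total(self) -> int:
        return len(self)

    def cis_mask(self, chrom: str | None = None) -> np.ndarray:
        m = self.chrom1 == self.chrom2
        if chrom is not None:
            m &= self.chrom1 == chrom
        return m.astype(bool)

    def subset(self, index: np.ndarray, sample_id: str | None = None) -> "PETSet":
        return PETSet(
            sample_id or self.sample_id,
            self.chrom1[index],
            self.pos1[index],
            self.chrom2[index],
            self.pos2[index],
        )


def combine_petsets(petsets: list[PETSet], sample_id: str) -> PETSet:
    """Concatenate replicate PET sets into one pooled sample."""
    return PETSet(
        sample_id,
        np.concatenate([p.chrom1 for p in petsets]),
        np.concatenate([p.pos1 for p in petsets]),
        np.concatenate([p.chrom2 for p in petsets]),
        np.concatenate([p.pos2 for p in petsets]),
    )


@dataclass(frozen=True)
class GenomeBins:
    """Fixed-width genomic bins, half-open [k*bin_size, (k+1)*bin_size), 0-based."""

    chrom_lengths: dict
    bin_size: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    def n_bins(self, chrom: str) -> int:
        return -(-int(self.chrom_lengths[chrom]) // self.bin_size)


@dataclass
class BinnedMatrix:
    """Symmetric binned contact matrix for one chromosome.

    ``matrix`` is a scipy CSR matrix; raw matrices hold integer counts,
    normalized ones floats. ``mask`` flags bins with zero raw coverage.
    """

    chrom: str
    bin_size: int
    matrix: sparse.csr_matrix
    normalized: bool = False
    norm_vector: np.ndarray | None = None
    mask: np.ndarray | None = field(default=None)  # True = bin masked (no coverage)

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def toarray(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())


def read_pairs(path, dialect: str = "pairs4", sample_id: str | None = None) -> PETSet:
    """Read a PET set from text.

    dialect "pairs4": chrom1 pos1 chrom2 pos2 (tab/space separated).
    dialect "bedpe": 6+ columns; the two interval *start* coordinates are
    used as PET positions. Lines starting with '#' are ignored.
    """
    if dialect not in ("pairs4", "bedpe"):
        raise ValueError(f"unknown dialect {dialect!r}")
    ncol = 4 if dialect == "pairs4" else 6
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < ncol:
                raise ValueError(f"{path}: malformed line {lineno}: expected >= {ncol} fields")
            try:
                if dialect == "pairs4":
                    rows.append((parts[0], int(parts[1]), parts[2], int(parts[3])))
                else:
                    rows.append((parts[0], int(parts[1]), parts[3], int(parts[4])))
            except ValueError as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from None
    if not rows:
        empty = np.array([], dtype=object)
        return PETSet(sample_id or str(path), empty, np.array([], int), empty, np.array([], int))
    c1, p1, c2, p2 = zip(*rows)
    return PETSet(sample_id or str(path), np.array(c1, object), np.array(p1), np.array(c2, object), np.array(p2))


def write_pairs(pets: PETSet, path) -> None:
    """Write a PET set as 4-column tab-separated pairs text."""
    df = pd.DataFrame(
        {"chrom1": pets.chrom1, "pos1": pets.pos1, "chrom2": pets.chrom2, "pos2": pets.pos2}
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def bin_pets(pets: PETSet, bins: GenomeBins, chrom: str) -> BinnedMatrix:
    """Bin cis PETs on ``chrom`` into a symmetric sparse count matrix.

    Bin index is floor(pos / bin_size); each PET increments M[i,j] and
    M[j,i] once. Trans PETs (and cis PETs on other chromosomes) are
    ignored with a logged tally.
    """
    n = bins.n_bins(chrom)
    cis = pets.cis_mask(chrom)
    n_skipped = len(pets) - int(cis.sum())
    if n_skipped:
        logger.info("bin_pets: %d PETs not cis on %s, skipped", n_skipped, chrom)
    p1 = pets.pos1[cis]
    p2 = pets.pos2[cis]
    length = int(bins.chrom_lengths[chrom])
    if len(p2) and (p2.max() >= length or p1.min() < 0):
        raise ValueError(f"PET position beyond {chrom} length {length}")
    i = p1 // bins.bin_size
    j = p2 // bins.bin_size
    off = i != j
    rows = np.concatenate([i, j[off]])
    cols = np.concatenate([j, i[off]])
    full = sparse.coo_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)), shape=(n, n)
    ).tocsr()
    coverage = np.asarray(full.sum(axis=1)).ravel()
    return BinnedMatrix(chrom, bins.bin_size, full, mask=coverage == 0)


def vc_sqrt_normalize(m: BinnedMatrix) -> BinnedMatrix:
    """Vanilla-coverage square-root normalization.

    With raw row sums c_i, M'[i,j] = M[i,j] / sqrt(c_i * c_j). Bins with
    zero coverage yield zero rows/columns and are flagged masked.
    """
    if m.normalized:
        raise ValueError("matrix is already normalized")
    coverage = np.asarray(m.matrix.sum(axis=1)).ravel().astype(float)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(coverage > 0, 1.0 / np.sqrt(coverage), 0.0)
    d = sparse.diags(inv_sqrt)
    normed = (d @ m.matrix.astype(float) @ d).tocsr()
    return BinnedMatrix(
        m.chrom,
        m.bin_size,
        normed,
        normalized=True,
        norm_vector=np.sqrt(coverage),
        mask=coverage == 0,
    )


def downsample_pets(petsets: list[PETSet], target: int, seed: int) -> list[PETSet]:
    """Down-sample every PET set to exactly ``target`` PETs without replacement."""
    if target < 0:
        raise ValueError("target must be >= 0")
    for p in petsets:
        if target > len(p):
            raise ValueError(
                f"target {target} exceeds size {len(p)} of sample {p.sample_id!r}"
            )
    rng = np.random.default_rng(seed)
    out = []
    for p in petsets:
        idx = rng.choice(len(p), size=target, replace=False)
        idx.sort()
        out.append(p.subset(idx))
    return out


@dataclass
class DistanceDensity:
    """Density of cis contact distances on the log10 scale plus band fractions."""

    log10_edges: np.ndarray
    density: np.ndarray  # integrates to 1 over log10(distance)
    band_edges: np.ndarray  # bp
    band_fractions: np.ndarray  # sums to 1; len(band_edges)+1 bands


def distance_density(
    pets: PETSet,
    band_edges=(10_000_000,),
    n_hist_bins: int = 100,
) -> DistanceDensity:
    """Decompose cis contact distances into a log10 density and band fractions.

    The default single band edge at 10 Mb separates compartment-scale
    interactions (>= 10 Mb) from TAD/loop-scale ones (< 10 Mb). PETs at
    distance 0 (same position / same bin diagonal in binned data) are
    excluded: distance 0 is undefined on a log scale.
    """
    band_edges = np.asarray(band_edges, dtype=float)
    if band_edges.ndim != 1 or np.any(np.diff(band_edges) <= 0):
        raise ValueError("band_edges must be strictly increasing")
    cis = pets.cis_mask()
    d = (pets.pos2[cis] - pets.pos1[cis]).astype(float)
    d = d[d > 0]
    if len(d) == 0:
        raise ValueError("no cis PETs with positive distance")
    logd = np.log10(d)
    density, edges = np.histogram(logd, bins=n_hist_bins, density=True)
    counts = np.histogram(d, bins=np.concatenate(([0.0], band_edges, [np.inf])))[0]
    return DistanceDensity(edges, density, band_edges, counts / counts.sum())
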