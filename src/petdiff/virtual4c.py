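"""Virtual 4C: one bait bin's row of a VC_SQRT-normalized 5-kb matrix.

The bait must align to exactly one bin of the matrix grid (e.g. the
5-kb bin chr12:113220000-113225000); multi-bin or off-grid baits are
rejected rather than summed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import BinnedMatrix

__all__ = ["V4CTrack", "virtual_4c", "parse_region", "write_bedgraph", "read_bedgraph"]


@dataclass
class V4CTrack:
    chrom: str
    bait_start: int
    bait_end: int
    bin_size: int
    values: np.ndarray  # per-bin normalized contact; NaN at masked bins
    sample_id: str
    all_masked: bool = False


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse "chrom:start-end" (e.g. "chr12:113220000-113225000")."""
    try:
        chrom, span = region.rsplit(":", 1)
        start, end = span.replace(",", "").split("-")
        return chrom, int(start), int(end)
    except ValueError:
        raise ValueError(f"cannot parse region {region!r}; expected chrom:start-end") from None


def virtual_4c(m: BinnedMatrix, bait: tuple[str, int, int], sample_id: str = "sample") -> V4CTrack:
    """Extract the bait bin's row of a VC_SQRT-normalized matrix as a track."""
    chrom, start, end = bait
    if not m.normalized:
        raise ValueError("virtual_4c expects a VC_SQRT-normalized matrix")
    if chrom != m.chrom:
        raise ValueError(f"bait chromosome {chrom!r} does not match matrix {m.chrom!r}")
    if start % m.bin_size != 0 or end - start != m.bin_size:
        raise ValueError(
            f"bait {chrom}:{start}-{end} must align to exactly one {m.bin_size}-bp bin; "
            "re-align the interval to the bin grid"
        )
    b = start // m.bin_size
    if not 0 <= b < m.n_bins:
        raise ValueError("bait bin outside the matrix")
    values = np.asarray(m.matrix[b].todense()).ravel().astype(float)
    if m.mask is not None:
        values = np.where(m.mask, np.nan, values)
    all_masked = bool(m.mask is not None and m.mask[b])
    if all_masked:
        values = np.full(m.n_bins, np.nan)
    return V4CTrack(m.chrom, start, end, m.bin_size, values, sample_id, all_masked)


def write_bedgraph(track: V4CTrack, path) -> None:
    valid = np.isfinite(track.values)
    starts = np.arange(len(track.values))[valid] * track.bin_size
    pd.DataFrame(
        {
            "chrom": track.chrom,
            "start": starts,
            "end": starts + track.bin_size,
            "value": [format(v, ".17g") for v in track.values[valid]],
        }
    ).to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path, n_bins: int, bin_size: int) -> np.ndarray:
    """Read a bedGraph written by :func:`write_bedgraph` back into a value array."""
    values = np.full(n_bins, np.nan)
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        float_precision="round_trip",
    )
    values[df["start"].to_numpy() // bin_size] = df["value"].to_numpy(dtype=float)
    return values
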