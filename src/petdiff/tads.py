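"""TAD enrichment scores and the two-pass MD comparison of TAD strength.

TAD strength is summarized by the enrichment score (ES): the number of
PETs falling exclusively inside a TAD (intra) divided by the number of
PETs with exactly one end inside it (inter). The ES matrix (TADs x
samples) feeds the same two-pass Mahalanobis test used for compartments;
significant TADs are labelled by which condition had the stronger mean ES.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import PETSet, downsample_pets
from .mahalanobis import FeatureMatrix, two_pass_md

__all__ = ["TAD", "TadES", "tad_es", "es_matrix", "compare_tads", "read_tads_bed", "write_tads_bed"]


@dataclass(frozen=True)
class TAD:
    chrom: str
    start: int
    end: int  # half-open
    id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"TAD {self.id or ''} has non-positive width")


@dataclass
class TadES:
    intra: int
    inter: int
    es: float
    zero_denominator: bool


def tad_es(pets: PETSet, tad: TAD) -> TadES:
    """Intra/inter PET counts and ES for one TAD (direct membership test).

    A PET end at exactly the TAD end coordinate is outside (half-open
    interval convention).
    """
    cis = pets.cis_mask(tad.chrom)
    in1 = cis & (pets.pos1 >= tad.start) & (pets.pos1 < tad.end)
    in2 = cis & (pets.pos2 >= tad.start) & (pets.pos2 < tad.end)
    intra = int((in1 & in2).sum())
    inter = int((in1 ^ in2).sum())
    return TadES(intra, inter, intra / max(inter, 1), inter == 0)


def _count_all_tads(pets: PETSet, tads: list[TAD]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized intra/inter counts for a sorted non-overlapping TAD list."""
    starts = np.array([t.start for t in tads], dtype=np.int64)
    ends = np.array([t.end for t in tads], dtype=np.int64)
    if np.any(starts[1:] < ends[:-1]):
        raise ValueError("TADs must be sorted and non-overlapping")
    chrom = tads[0].chrom
    cis = pets.cis_mask(chrom)
    p1, p2 = pets.pos1[cis], pets.pos2[cis]
    k = len(tads)

    def locate(pos):
        i = np.searchsorted(starts, pos, side="right") - 1
        ic = np.clip(i, 0, None)
        inside = (i >= 0) & (pos < ends[ic])
        return np.where(inside, ic, -1)

    t1 = locate(p1)
    t2 = locate(p2)
    both = (t1 >= 0) & (t1 == t2)
    intra = np.bincount(t1[both], minlength=k)
    one1 = (t1 >= 0) & ~both
    one2 = (t2 >= 0) & ~both & (t2 != t1)
    # a PET spanning two different TADs counts as "inter" for each of them
    inter = np.bincount(t1[one1], minlength=k) + np.bincount(t2[one2], minlength=k)
    return intra, inter


def es_matrix(
    petsets: list[PETSet],
    tads: list[TAD],
    conditions: list,
    equalize: bool = True,
    seed: int = 0,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Build the TADs x samples ES matrix.

    With ``equalize`` (the default, mirroring equal down-sampling of PET
    depth before comparison) all samples are first down-sampled to the
    common minimum. TADs with a zero-denominator flag in any sample are
    dropped and reported in the returned table.
    """
    if not tads:
        raise ValueError("empty TAD list")
    if len(petsets) < 2:
        raise ValueError("need at least 2 samples")
    tads = sorted(tads, key=lambda t: t.start)
    if equalize:
        target = min(len(p) for p in petsets)
        petsets = downsample_pets(petsets, target, seed)
    records = {}
    zero_flag = np.zeros(len(tads), dtype=bool)
    for p in petsets:
        intra, inter = _count_all_tads(p, tads)
        zero_flag |= inter == 0
        records[p.sample_id] = intra / np.maximum(inter, 1)
        records[f"{p.sample_id}:intra"] = intra
        records[f"{p.sample_id}:inter"] = inter
    table = pd.DataFrame(records, index=[t.id or f"tad_{i}" for i, t in enumerate(tads)])
    table["dropped_zero_denominator"] = zero_flag
    keep = ~zero_flag
    fm = FeatureMatrix(
        feature_ids=table.index.to_numpy()[keep],
        sample_ids=[p.sample_id for p in petsets],
        conditions=list(conditions),
        X=np.column_stack([records[p.sample_id][keep] for p in petsets]),
    )
    return fm, table


def compare_tads(fm: FeatureMatrix, alpha: float = 0.01) -> pd.DataFrame:
    """Two-pass MD test on the ES matrix; label significant TADs by direction.

    A significant TAD is "condition1-specific" when the condition-1 mean
    ES exceeds the condition-2 mean (i.e. the TAD is stronger in condition
    1), and "condition2-specific" otherwise.
    """
    result = two_pass_md(fm, alpha=alpha)
    means = fm.condition_means()
    c1, c2 = list(means)[0], list(means)[1]
    direction = np.where(means[c1] > means[c2], "condition1-specific", "condition2-specific")
    direction = np.where(result.significant, direction, "unchanged")
    out = pd.DataFrame(
        {
            "tad_id": fm.feature_ids,
            "md_pass1": result.md_pass1,
            "md": result.md_pass2,
            "pvalue": result.pvalues,
            "significant": result.significant,
            "direction": direction,
        }
    )
    for sid, col in zip(fm.sample_ids, fm.X.T):
        out[f"es_{sid}"] = col
    return out


def read_tads_bed(path, id_prefix: str = "tad") -> list[TAD]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        name = str(row[3]) if len(row) > 3 else f"{id_prefix}_{i}"
        out.append(TAD(str(row[0]), int(row[1]), int(row[2]), name))
    return out


def write_tads_bed(tads: list[TAD], path) -> None:
    pd.DataFrame(
        {
            "chrom": [t.chrom for t in tads],
            "start": [t.start for t in tads],
            "end": [t.end for t in tads],
            "name": [t.id for t in tads],
        }
    ).to_csv(path, sep="\t", header=False, index=False)
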