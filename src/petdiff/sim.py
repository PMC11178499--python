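"""Synthetic two-condition, replicated PET and peak-count generator.

The generator emulates the statistical structure of deep proximity-ligation
data at desk scale: a power-law contact-distance decay, checkerboard A/B
compartment enrichment, intra-TAD enrichment, focal loop anchors, two
conditions with replicates, and Poisson peak-level read counts for the
differential ChIP-seq test. Condition 2 differs from condition 1 by an
explicit edit list (flipped compartment blocks, scaled TAD enrichments,
scaled loop strengths), which doubles as the ground truth for recovery
benchmarks.

Sampling model for one PET: draw a genomic distance d from the truncated
power law p(d) ~ d^-alpha on [min_distance, chrom_length), draw the left
end uniformly, and accept/reject with weight

    w = same_compartment_weight^[ends share a compartment label]
        * tad_enrichment^[both ends inside the same TAD]
        * loop_strength^[ends fall within `width` of a loop anchor pair].

Everything is a pure function of (config, condition, replicate).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .contacts import PETSet

__all__ = [
    "Block",
    "Tad",
    "Loop",
    "Edit",
    "SimConfig",
    "GroundTruth",
    "PeakCountTable",
    "simulate_pets",
    "simulate_peak_counts",
    "make_default_scenario",
    "sample_truncated_power_law",
    "power_law_cdf",
]

_BATCH = 1 << 21  # fixed proposal batch size keeps output deterministic


@dataclass(frozen=True)
class Block:
    start: int
    end: int
    label: str  # "A" | "B"


@dataclass(frozen=True)
class Tad:
    start: int
    end: int
    enrichment: float = 1.0


@dataclass(frozen=True)
class Loop:
    anchor1: int
    anchor2: int
    strength: float = 1.0
    width: int = 2000


@dataclass(frozen=True)
class Edit:
    """One condition-2 edit: flip a block label, or scale a TAD/loop factor."""

    kind: str  # "flip_block" | "scale_tad" | "scale_loop"
    index: int
    factor: float = 1.0


@dataclass(frozen=True)
class SimConfig:
    chrom_name: str
    chrom_length: int
    n_pets: int
    decay_exponent: float
    compartment_blocks: tuple
    same_compartment_weight: float
    tads: tuple = ()
    loops: tuple = ()
    condition2_edits: tuple = ()
    replicates_per_condition: int = 2
    base_seed: int = 13
    min_distance: int = 1000

    def __post_init__(self) -> None:
        if self.n_pets <= 0:
            raise ValueError("n_pets must be positive")
        if self.same_compartment_weight < 1:
            raise ValueError("same_compartment_weight must be >= 1")
        blocks = self.compartment_blocks
        if not blocks:
            raise ValueError("compartment_blocks must be non-empty")
        pos = 0
        for b in blocks:
            if b.start != pos or b.end <= b.start:
                raise ValueError("compartment_blocks must tile [0, chrom_length) without overlap")
            pos = b.end
        if pos != self.chrom_length:
            raise ValueError("compartment_blocks must tile the full chromosome")
        prev_end = -1
        for t in sorted(self.tads, key=lambda t: t.start):
            if t.start < prev_end or t.end <= t.start:
                raise ValueError("TADs must be non-overlapping with positive length")
            if t.enrichment <= 0:
                raise ValueError("TAD enrichment factors must be strictly positive")
            prev_end = t.end
        for lp in self.loops:
            if lp.strength <= 0 or lp.width <= 0:
                raise ValueError("loop strength and width must be strictly positive")
            if not (0 <= lp.anchor1 < lp.anchor2 < self.chrom_length):
                raise ValueError("loop anchors must be ordered and on the chromosome")

    def condition_view(self, condition: int):
        """Blocks/TADs/loops with condition-2 edits applied when condition == 2."""
        blocks = list(self.compartment_blocks)
        tads = list(self.tads)
        loops = list(self.loops)
        if condition == 2:
            for e in self.condition2_edits:
                if e.kind == "flip_block":
                    b = blocks[e.index]
                    blocks[e.index] = replace(b, label="B" if b.label == "A" else "A")
                elif e.kind == "scale_tad":
                    tads[e.index] = replace(tads[e.index], enrichment=tads[e.index].enrichment * e.factor)
                elif e.kind == "scale_loop":
                    loops[e.index] = replace(loops[e.index], strength=loops[e.index].strength * e.factor)
                else:
                    raise ValueError(f"unknown edit kind {e.kind!r}")
        elif condition != 1:
            raise ValueError("condition must be 1 or 2")
        return blocks, tads, loops


@dataclass(frozen=True)
class GroundTruth:
    """The condition-2 edits re-expressed as genomic intervals / anchors."""

    flipped_blocks: tuple  # (start, end) intervals
    weakened_tads: tuple  # (start, end, true factor)
    perturbed_loops: tuple  # (anchor1, anchor2, true factor)

    @classmethod
    def from_config(cls, config: SimConfig) -> "GroundTruth":
        flips, wtads, ploops = [], [], []
        for e in config.condition2_edits:
            if e.kind == "flip_block":
                b = config.compartment_blocks[e.index]
                flips.append((b.start, b.end))
            elif e.kind == "scale_tad":
                t = config.tads[e.index]
                wtads.append((t.start, t.end, e.factor))
            elif e.kind == "scale_loop":
                lp = config.loops[e.index]
                ploops.append((lp.anchor1, lp.anchor2, e.factor))
        return cls(tuple(flips), tuple(wtads), tuple(ploops))


def power_law_cdf(d, alpha: float, dmin: float, dmax: float):
    """CDF of the truncated power law p(d) ~ d^-alpha on [dmin, dmax]."""
    d = np.asarray(d, dtype=float)
    if alpha == 1.0:
        return np.log(d / dmin) / np.log(dmax / dmin)
    a = 1.0 - alpha
    return (d**a - dmin**a) / (dmax**a - dmin**a)


def sample_truncated_power_law(u, alpha: float, dmin: float, dmax: float):
    """Inverse-CDF sampling of the truncated power law from uniforms ``u``."""
    u = np.asarray(u, dtype=float)
    if alpha == 1.0:
        return dmin * (dmax / dmin) ** u
    a = 1.0 - alpha
    return (dmin**a + u * (dmax**a - dmin**a)) ** (1.0 / a)


def _replicate_rng(config: SimConfig, condition: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.base_seed), int(condition), int(replicate)])
    )


def simulate_pets(config: SimConfig, condition: int, replicate: int) -> PETSet:
    """Draw one replicate's worth of intra-chromosomal PETs by rejection sampling."""
    if not 0 <= replicate < config.replicates_per_condition:
        raise ValueError("replicate index out of range")
    blocks, tads, loops = config.condition_view(condition)
    rng = _replicate_rng(config, condition, replicate)
    L = config.chrom_length
    scw = config.same_compartment_weight

    block_starts = np.array([b.start for b in blocks], dtype=np.int64)
    block_labels = np.array([0 if b.label == "A" else 1 for b in blocks], dtype=np.int8)

    tads_sorted = sorted(tads, key=lambda t: t.start)
    tad_starts = np.array([t.start for t in tads_sorted], dtype=np.int64)
    tad_ends = np.array([t.end for t in tads_sorted], dtype=np.int64)
    tad_factors = np.array([t.enrichment for t in tads_sorted], dtype=float)

    loops_sorted = sorted(loops, key=lambda lp: lp.anchor1)
    win_starts = np.array([lp.anchor1 - lp.width for lp in loops_sorted], dtype=np.int64)
    loop_a1 = np.array([lp.anchor1 for lp in loops_sorted], dtype=np.int64)
    loop_a2 = np.array([lp.anchor2 for lp in loops_sorted], dtype=np.int64)
    loop_w = np.array([lp.width for lp in loops_sorted], dtype=np.int64)
    loop_s = np.array([lp.strength for lp in loops_sorted], dtype=float)
    if len(win_starts) > 1 and np.any((loop_a1[:-1] + loop_w[:-1]) >= win_starts[1:]):
        raise ValueError("loop anchor1 windows must not overlap")

    wmax = scw
    if len(tad_factors):
        wmax *= max(1.0, tad_factors.max())
    if len(loop_s):
        wmax *= max(1.0, loop_s.max())

    out1: list[np.ndarray] = []
    out2: list[np.ndarray] = []
    n_acc = 0
    n_prop = 0
    while n_acc < config.n_pets:
        d = sample_truncated_power_law(
            rng.random(_BATCH), config.decay_exponent, config.min_distance, L - 1
        )
        d = np.rint(d).astype(np.int64)
        np.clip(d, config.min_distance, L - 1, out=d)
        p1 = rng.integers(0, L - d)
        p2 = p1 + d

        w = np.ones(_BATCH)
        lab1 = block_labels[np.searchsorted(block_starts, p1, side="right") - 1]
        lab2 = block_labels[np.searchsorted(block_starts, p2, side="right") - 1]
        w[lab1 == lab2] *= scw

        if len(tad_starts):
            t1 = np.searchsorted(tad_starts, p1, side="right") - 1
            t2 = np.searchsorted(tad_starts, p2, side="right") - 1
            t1c = np.clip(t1, 0, None)
            t2c = np.clip(t2, 0, None)
            same_tad = (
                (t1 >= 0) & (t1 == t2) & (p1 < tad_ends[t1c]) & (p2 < tad_ends[t2c])
            )
            w[same_tad] *= tad_factors[t1c[same_tad]]

        if len(win_starts):
            li = np.searchsorted(win_starts, p1, side="right") - 1
            lic = np.clip(li, 0, None)
            hit = (
                (li >= 0)
                & (np.abs(p1 - loop_a1[lic]) <= loop_w[lic])
                & (np.abs(p2 - loop_a2[lic]) <= loop_w[lic])
            )
            w[hit] *= loop_s[lic[hit]]

        accept = rng.random(_BATCH) * wmax < w
        out1.append(p1[accept])
        out2.append(p2[accept])
        n_acc += int(accept.sum())
        n_prop += _BATCH
        if n_prop >= 8 * _BATCH and n_acc / n_prop < 1e-3:
            raise RuntimeError(
                f"rejection-sampling acceptance rate {n_acc / n_prop:.2e} < 1e-3; "
                "reduce the maximum enrichment weight or loop strength"
            )

    pos1 = np.concatenate(out1)[: config.n_pets]
    pos2 = np.concatenate(out2)[: config.n_pets]
    chrom = np.full(config.n_pets, config.chrom_name, dtype=object)
    return PETSet(
        f"cond{condition}_rep{replicate}", chrom, pos1, chrom.copy(), pos2
    )


@dataclass
class PeakCountTable:
    """Per-peak raw counts across samples plus simulation truth labels."""

    peaks: pd.DataFrame  # peak_id, chrom, start, end
    counts: pd.DataFrame  # one column per sample
    conditions: list  # condition (1|2) per counts column
    sample_totals: np.ndarray
    truth: np.ndarray  # "shared" | "condition2_up" | "condition2_down"


def simulate_peak_counts(
    n_peaks: int,
    depth_per_sample: float,
    diff_fraction: float,
    fold_change: float,
    seed: int,
    replicates_per_condition: int = 2,
    frip: float = 0.3,
    dispersion_sigma: float = 0.8,
) -> PeakCountTable:
    """Simulate Poisson peak read counts for two conditions with replicates.

    Per-peak base rates are log-normal (sigma ``dispersion_sigma``), scaled
    so that expected peak reads sum to ``frip * depth_per_sample``. A
    ``diff_fraction`` subset has its condition-2 mean multiplied (half up,
    half down) by ``fold_change``. Replicate counts are independent Poisson
    draws.
    """
    if not 0 <= diff_fraction <= 1:
        raise ValueError("diff_fraction must be in [0, 1]")
    if fold_change < 1:
        raise ValueError("fold_change must be >= 1")
    if depth_per_sample <= 0:
        raise ValueError("depth_per_sample must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 97]))
    base = rng.lognormal(mean=0.0, sigma=dispersion_sigma, size=n_peaks)
    base *= frip * depth_per_sample / base.sum()

    truth = np.full(n_peaks, "shared", dtype=object)
    n_diff = int(round(diff_fraction * n_peaks))
    diff_idx = rng.choice(n_peaks, size=n_diff, replace=False)
    up = diff_idx[: n_diff // 2]
    down = diff_idx[n_diff // 2 :]
    truth[up] = "condition2_up"
    truth[down] = "condition2_down"

    mean2 = base.copy()
    mean2[up] *= fold_change
    mean2[down] /= fold_change

    cols, conditions, totals = {}, [], []
    for cond, mean in ((1, base), (2, mean2)):
        for rep in range(replicates_per_condition):
            counts = rng.poisson(mean)
            name = f"cond{cond}_rep{rep}"
            cols[name] = counts
            conditions.append(cond)
            totals.append(counts.sum())
    peaks = pd.DataFrame(
        {
            "peak_id": [f"peak_{i}" for i in range(n_peaks)],
            "chrom": "chrSim",
            "start": np.arange(n_peaks) * 3000,
            "end": np.arange(n_peaks) * 3000 + 500,
        }
    )
    return PeakCountTable(
        peaks, pd.DataFrame(cols), conditions, np.array(totals, dtype=np.int64), truth
    )


def make_default_scenario(
    n_pets: int = 1_000_000, base_seed: int = 13
) -> tuple[SimConfig, GroundTruth]:
    """The documented 60-Mb single-chromosome benchmark scenario.

    Layout (all coordinates deterministic):

    * 30 alternating A/B compartment blocks: ten groups of
      [2.8 Mb, 0.4 Mb, 2.8 Mb]; the ten 0.4-Mb mid-group blocks flip their
      label in condition 2. Switched loci are deliberately sub-Mb — a small
      minority of 100-kb bins — because compartment switching is an
      outlier phenomenon: the Mahalanobis test presumes that switched bins
      are rare relative to the stable background.
    * 100 TADs (sizes cycling 300/400/500/600 kb, 150-kb gaps, enrichment
      2.0); ten of them (every tenth starting at index 5) are weakened
      x0.5 in condition 2.
    * 50 loops, one per even-indexed TAD, with 50-kb anchor separation
      (inside the +/-100-kb viewpoint background window), strength 40 at
      2-kb anchor width; ten (every fifth starting at index 2) are
      weakened x0.25 in condition 2. Loop anchors double as the 50
      viewpoints of the HiChIP viewpoint analysis.
    * distance decay alpha = 1, same-compartment weight 2.0,
      2 replicates x ``n_pets`` PETs per condition.
    """
    mb = 1_000_000
    sizes = []
    for _ in range(10):
        sizes += [int(2.8 * mb), int(0.4 * mb), int(2.8 * mb)]
    blocks = []
    pos = 0
    for i, size in enumerate(sizes):
        blocks.append(Block(pos, pos + size, "A" if i % 2 == 0 else "B"))
        pos += size
    flip_idx = [3 * g + 1 for g in range(10)]

    tad_sizes = [300_000, 400_000, 500_000, 600_000]
    tads = []
    pos = 0
    for k in range(100):
        pos += 150_000
        size = tad_sizes[k % 4]
        tads.append(Tad(pos, pos + size, enrichment=2.0))
        pos += size
    weakened_idx = list(range(5, 100, 10))

    loops = []
    for k in range(50):
        a1 = tads[2 * k].start + 40_000
        loops.append(Loop(a1, a1 + 50_000, strength=40.0, width=2000))
    perturbed_idx = list(range(2, 50, 5))

    edits = (
        [Edit("flip_block", i) for i in flip_idx]
        + [Edit("scale_tad", i, 0.5) for i in weakened_idx]
        + [Edit("scale_loop", i, 0.25) for i in perturbed_idx]
    )
    config = SimConfig(
        chrom_name="chrSim",
        chrom_length=60 * mb,
        n_pets=n_pets,
        decay_exponent=1.0,
        compartment_blocks=tuple(blocks),
        same_compartment_weight=2.0,
        tads=tuple(tads),
        loops=tuple(loops),
        condition2_edits=tuple(edits),
        replicates_per_condition=2,
        base_seed=base_seed,
    )
    return config, GroundTruth.from_config(config)
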