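"""End-to-end orchestration: simulate -> matrices -> differential statistics.

``run_all`` executes the whole synthetic benchmark: PET simulation for two
conditions x replicates, compartment PC1 and two-pass MD switch calls,
TAD ES comparison, HiChIP-style viewpoint enrichment, virtual 4C, and the
Poisson differential peak test, and writes a machine-readable summary
JSON with per-stage counts and recovery-versus-ground-truth metrics. The
run is a pure function of the config (fixed seed => byte-identical
summary).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import compartments as comp
from . import contacts, sim, tads, viewpoints, virtual4c
from .mahalanobis import FeatureMatrix, classify_compartment_switch, two_pass_md
from .peaks import classify_peaks, normalize_to_depth

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "truth_flip_bin_mask", "truth_reference_track"]


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 13
    n_pets: int = 1_000_000
    alpha: float = 0.01
    compartment_bin_size: int = 100_000
    viewpoint_bin_size: int = 1_000
    viewpoint_window: int = 100_000
    v4c_bin_size: int = 5_000
    peak_p_cut: float = 1e-5
    peak_fc_cut: float = 2.0
    n_peaks: int = 10_000
    peak_depth: float = 30_000_000.0
    peak_diff_fraction: float = 0.1
    peak_fold_change: float = 4.0
    write_intermediates: bool = False

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def truth_flip_bin_mask(truth: sim.GroundTruth, n_bins: int, bin_size: int) -> np.ndarray:
    """Boolean mask of bins inside ground-truth flipped blocks."""
    mask = np.zeros(n_bins, dtype=bool)
    for start, end in truth.flipped_blocks:
        mask[start // bin_size : -(-end // bin_size)] = True
    return mask


def truth_reference_track(config: sim.SimConfig, bin_size: int) -> np.ndarray:
    """+1/-1 per-bin covariate from condition-1 A/B labels (A positive).

    Used as the shared orientation reference for every sample's PC1.
    """
    n = -(-config.chrom_length // bin_size)
    ref = np.empty(n)
    starts = np.arange(n) * bin_size + bin_size // 2
    block_starts = np.array([b.start for b in config.compartment_blocks])
    labels = np.array([1.0 if b.label == "A" else -1.0 for b in config.compartment_blocks])
    ref = labels[np.searchsorted(block_starts, starts, side="right") - 1]
    return ref


def _round(x, nd: int = 6):
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    if isinstance(x, (float, np.floating)):
        return round(float(x), nd) if np.isfinite(x) else None
    if isinstance(x, (int, np.integer)):
        return int(x)
    return x


def _compartment_stage(cfg, config, truth, petsets):
    bins = contacts.GenomeBins({config.chrom_name: config.chrom_length}, cfg.compartment_bin_size)
    reference = truth_reference_track(config, cfg.compartment_bin_size)
    tracks = {}
    for (cond, rep), pets in petsets.items():
        m = contacts.bin_pets(pets, bins, config.chrom_name)
        oe = comp.observed_over_expected(m)
        track = comp.compute_pc1(
            oe, config.chrom_name, cfg.compartment_bin_size, sample_id=pets.sample_id
        )
        tracks[(cond, rep)] = comp.orient_pc1(track, reference)
    n_bins = bins.n_bins(config.chrom_name)
    valid = np.all([t.valid for t in tracks.values()], axis=0)
    cond_means = {}
    for cond in (1, 2):
        reps = [tracks[(cond, r)].values for r in range(config.replicates_per_condition)]
        cond_means[cond] = np.mean(reps, axis=0)
    X = np.column_stack([cond_means[1][valid], cond_means[2][valid]])
    fm = FeatureMatrix(
        feature_ids=np.where(valid)[0],
        sample_ids=["condition1", "condition2"],
        conditions=[1, 2],
        X=X,
    )
    result = two_pass_md(fm, alpha=cfg.alpha)
    categories, counts = classify_compartment_switch(result, X[:, 0], X[:, 1])

    flip_mask_all = truth_flip_bin_mask(truth, n_bins, cfg.compartment_bin_size)
    flip_mask = flip_mask_all[valid]
    is_switch = np.isin(categories, ["A->B", "B->A"])
    recall = float(is_switch[flip_mask].mean()) if flip_mask.any() else float("nan")
    precision = float(flip_mask[is_switch].mean()) if is_switch.any() else float("nan")

    # PC1 sign agreement with each condition's own truth labels
    agreements = []
    for (cond, rep), track in tracks.items():
        blocks, _, _ = config.condition_view(cond)
        starts = np.array([b.start for b in blocks])
        labels = np.array([1.0 if b.label == "A" else -1.0 for b in blocks])
        centers = np.arange(n_bins) * cfg.compartment_bin_size + cfg.compartment_bin_size // 2
        truth_sign = labels[np.searchsorted(starts, centers, side="right") - 1]
        v = track.valid
        agreements.append(float((np.sign(track.values[v]) == truth_sign[v]).mean()))
    stage = {
        "n_bins_tested": int(valid.sum()),
        "n_significant": int(result.significant.sum()),
        "quadrant_counts": counts,
        "flip_recall": recall,
        "switch_precision": precision,
        "pc1_truth_agreement_min": min(agreements),
        "pc1_truth_agreement_mean": float(np.mean(agreements)),
    }
    return stage, tracks, categories, fm


def _tad_stage(cfg, config, truth, pooled):
    tad_list = [
        tads.TAD(config.chrom_name, t.start, t.end, f"tad_{i}")
        for i, t in enumerate(config.tads)
    ]
    fm, _table = tads.es_matrix(
        list(pooled.values()), tad_list, conditions=[1, 2], equalize=True, seed=cfg.seed + 101
    )
    table = tads.compare_tads(fm, alpha=cfg.alpha)
    weakened_ids = {
        f"tad_{i}" for i, e in enumerate(config.tads)
        if any(ws == e.start for ws, _we, _f in truth.weakened_tads)
    }
    called_weaker = set(table.loc[table["direction"] == "condition1-specific", "tad_id"])
    detected = len(weakened_ids & called_weaker)
    false_pos = int(
        (table.loc[~table["tad_id"].isin(weakened_ids), "significant"]).sum()
    )
    stage = {
        "n_tads_tested": int(len(table)),
        "n_significant": int(table["significant"].sum()),
        "n_condition1_specific": int((table["direction"] == "condition1-specific").sum()),
        "n_condition2_specific": int((table["direction"] == "condition2-specific").sum()),
        "weakened_detected": detected,
        "weakened_total": len(weakened_ids),
        "false_positives": false_pos,
    }
    return stage, table


def scenario_viewpoints(config: sim.SimConfig) -> list[viewpoints.Viewpoint]:
    """Loop anchor-1 midpoints as viewpoints, categorized by perturbation."""
    perturbed = {config.loops[e.index].anchor1 for e in config.condition2_edits if e.kind == "scale_loop"}
    return [
        viewpoints.Viewpoint(
            f"vp_{i}",
            config.chrom_name,
            lp.anchor1,
            "perturbed" if lp.anchor1 in perturbed else "stable",
        )
        for i, lp in enumerate(config.loops)
    ]


def _viewpoint_stage(cfg, config, pooled):
    bins = contacts.GenomeBins({config.chrom_name: config.chrom_length}, cfg.viewpoint_bin_size)
    vps = scenario_viewpoints(config)
    rows = []
    for cond, pets in pooled.items():
        m = contacts.bin_pets(pets, bins, config.chrom_name)
        for vp in vps:
            rec = viewpoints.viewpoint_es(m, vp, window_bp=cfg.viewpoint_window)
            rows.append(
                {
                    "viewpoint_id": vp.id,
                    "category": vp.category,
                    "sample_id": pets.sample_id,
                    "condition": cond,
                    "es": rec.es,
                }
            )
    records = pd.DataFrame(rows)
    means, diffs = viewpoints.es_by_category(records)
    pert = diffs.loc[diffs["category"] == "perturbed", "es_diff"].to_numpy()
    # loops weakened in condition 2 => ES should drop: test cond1 - cond2 > 0
    wstat = stats.wilcoxon(-pert, alternative="greater") if len(pert) >= 5 else None
    stage = {
        "n_viewpoints": len(vps),
        "mean_es": {
            f"{cat_}|{samp}": float(means.loc[cat_, samp])
            for cat_ in means.index
            for samp in means.columns
        },
        "perturbed_wilcoxon_p": float(wstat.pvalue) if wstat else float("nan"),
        "perturbed_mean_diff_cond1_minus_cond2": float(-pert.mean()) if len(pert) else float("nan"),
    }
    return stage, records


def _v4c_stage(cfg, config, pooled):
    bins = contacts.GenomeBins({config.chrom_name: config.chrom_length}, cfg.v4c_bin_size)
    perturbed_loops = [config.loops[e.index] for e in config.condition2_edits if e.kind == "scale_loop"]
    lp = perturbed_loops[0] if perturbed_loops else config.loops[0]
    bait_start = (lp.anchor1 // cfg.v4c_bin_size) * cfg.v4c_bin_size
    bait = (config.chrom_name, bait_start, bait_start + cfg.v4c_bin_size)
    anchor_bin = lp.anchor2 // cfg.v4c_bin_size
    stage = {"bait": f"{bait[0]}:{bait[1]}-{bait[2]}"}
    tracks = {}
    for cond, pets in pooled.items():
        m = contacts.vc_sqrt_normalize(contacts.bin_pets(pets, bins, config.chrom_name))
        track = virtual4c.virtual_4c(m, bait, sample_id=pets.sample_id)
        tracks[cond] = track
        flank = np.concatenate(
            [
                track.values[max(0, anchor_bin - 50) : anchor_bin - 2],
                track.values[anchor_bin + 3 : anchor_bin + 51],
            ]
        )
        # mean, not median: far from the anchor the 5-kb bins hold < 1 count
        # each at desk-scale depth, so the median background is often 0
        level = np.nanmean(flank)
        ratio = float(track.values[anchor_bin] / level) if level > 0 else float("nan")
        stage[f"anchor_over_flank_cond{cond}"] = ratio
    return stage, tracks


def _peak_stage(cfg):
    table = sim.simulate_peak_counts(
        cfg.n_peaks,
        cfg.peak_depth,
        cfg.peak_diff_fraction,
        cfg.peak_fold_change,
        seed=cfg.seed + 7,
    )
    conds = np.asarray(table.conditions)
    norm = normalize_to_depth(table.counts.to_numpy(), table.sample_totals[None, :])
    mean1 = norm[:, conds == 1].mean(axis=1)
    mean2 = norm[:, conds == 2].mean(axis=1)
    res = classify_peaks(mean1, mean2, p_cut=cfg.peak_p_cut, fc_cut=cfg.peak_fc_cut)
    truth = table.truth
    is_diff = truth != "shared"
    correct = (
        ((truth == "condition2_up") & (res["class"] == "condition2-selective"))
        | ((truth == "condition2_down") & (res["class"] == "condition1-selective"))
    ).to_numpy()
    sensitivity = float(correct[is_diff].mean()) if is_diff.any() else float("nan")
    fpr = float((res["class"][~is_diff] != "shared").mean()) if (~is_diff).any() else float("nan")
    stage = {
        "n_peaks": cfg.n_peaks,
        "class_counts": res["class"].value_counts().to_dict(),
        "sensitivity": sensitivity,
        "false_positive_rate": fpr,
    }
    return stage, res


def run_all(cfg: RunConfig) -> dict:
    """Run the full synthetic-to-results benchmark and write summary JSON."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    config, truth = sim.make_default_scenario(n_pets=cfg.n_pets, base_seed=cfg.seed)

    logger.info("stage simulate: %d PETs x 2 conditions x %d replicates",
                config.n_pets, config.replicates_per_condition)
    petsets = {
        (cond, rep): sim.simulate_pets(config, cond, rep)
        for cond in (1, 2)
        for rep in range(config.replicates_per_condition)
    }
    if cfg.write_intermediates:
        for (cond, rep), pets in petsets.items():
            contacts.write_pairs(pets, os.path.join(cfg.out_dir, f"{pets.sample_id}.pairs"))

    # pooled per condition, equal down-sampled across conditions
    pooled_raw = {
        cond: contacts.combine_petsets(
            [petsets[(cond, r)] for r in range(config.replicates_per_condition)],
            f"condition{cond}",
        )
        for cond in (1, 2)
    }
    target = min(len(p) for p in pooled_raw.values())
    eq = contacts.downsample_pets(list(pooled_raw.values()), target, seed=cfg.seed + 3)
    pooled = dict(zip(pooled_raw.keys(), eq))

    summary = {"config": {"seed": cfg.seed, "n_pets": cfg.n_pets, "alpha": cfg.alpha}}

    dd = {
        cond: contacts.distance_density(p).band_fractions
        for cond, p in pooled.items()
    }
    summary["distance_bands"] = {
        f"cond{cond}_fraction_ge_10Mb": float(v[1]) for cond, v in dd.items()
    }

    logger.info("stage compartments")
    summary["compartments"], tracks, categories, comp_fm = _compartment_stage(
        cfg, config, truth, petsets
    )
    logger.info("stage tads")
    summary["tads"], tad_table = _tad_stage(cfg, config, truth, pooled)
    logger.info("stage viewpoints")
    summary["viewpoints"], vp_records = _viewpoint_stage(cfg, config, pooled)
    logger.info("stage virtual4c")
    summary["virtual4c"], v4c_tracks = _v4c_stage(cfg, config, pooled)
    logger.info("stage diff_peaks")
    summary["diff_peaks"], peak_table = _peak_stage(cfg)

    if cfg.write_intermediates:
        tad_table.to_csv(os.path.join(cfg.out_dir, "tad_comparison.tsv"), sep="\t", index=False)
        vp_records.to_csv(os.path.join(cfg.out_dir, "viewpoint_es.tsv"), sep="\t", index=False)
        peak_table.to_csv(os.path.join(cfg.out_dir, "diff_peaks.tsv"), sep="\t", index=False)
        for cond, track in v4c_tracks.items():
            virtual4c.write_bedgraph(
                track, os.path.join(cfg.out_dir, f"v4c_condition{cond}.bedgraph")
            )
        for track in tracks.values():
            track.to_bedgraph(os.path.join(cfg.out_dir, f"pc1_{track.sample_id}.bedgraph"))

    summary = _round(summary)
    with open(os.path.join(cfg.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
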