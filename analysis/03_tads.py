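#!/usr/bin/env python
"""Compare TAD strength (enrichment score) between conditions.

Pools replicates per condition, down-samples both pools to equal PET
depth, computes per-TAD ES = intra-PETs / one-end PETs for the 100
scenario TADs, and runs the two-pass Mahalanobis comparison (one-sided
chi-squared, P < 0.01). Reports how many of the 10 planted half-strength
TADs are recovered as condition1-specific.
"""

import argparse
import os

import pandas as pd

from petdiff import contacts, sim
from petdiff.pipeline import RunConfig, _tad_stage


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-pets", type=int, default=1_000_000)
    ap.add_argument("--data-dir", default="scratch/data")
    ap.add_argument("--results-dir", default="results")
    args = ap.parse_args()

    config, truth = sim.make_default_scenario(n_pets=args.n_pets, base_seed=args.seed)
    pooled = {}
    for cond in (1, 2):
        reps = [
            contacts.read_pairs(
                os.path.join(args.data_dir, f"cond{cond}_rep{r}.pairs"),
                sample_id=f"cond{cond}_rep{r}",
            )
            for r in range(config.replicates_per_condition)
        ]
        pooled[cond] = contacts.combine_petsets(reps, f"condition{cond}")

    cfg = RunConfig(out_dir=args.results_dir, seed=args.seed, n_pets=args.n_pets)
    stage, table = _tad_stage(cfg, config, truth, pooled)
    table.to_csv(os.path.join(args.results_dir, "tad_comparison.tsv"), sep="\t", index=False)

    print(f"TADs tested: {stage['n_tads_tested']}, significant: {stage['n_significant']} "
          f"({stage['n_condition1_specific']} condition1-specific, "
          f"{stage['n_condition2_specific']} condition2-specific)")
    print(f"planted half-strength TADs recovered: {stage['weakened_detected']}/10, "
          f"false positives: {stage['false_positives']}")


if __name__ == "__main__":
    main()
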