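#!/usr/bin/env python
"""Simulate the two-condition benchmark contact data set.

Generates the default 60-Mb scenario (2 conditions x 2 replicates of
intra-chromosomal PETs, with 10 flipped compartment blocks, 10
half-strength TADs and 10 quarter-strength loops in condition 2), writes
the PET lists as pairs text under scratch/data/ and the ground truth +
interval annotations under results/.
"""

import argparse
import json
import os

import pandas as pd

from petdiff import contacts, sim


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-pets", type=int, default=1_000_000)
    ap.add_argument("--data-dir", default="scratch/data")
    ap.add_argument("--results-dir", default="results")
    args = ap.parse_args()

    os.makedirs(args.data_dir, exist_ok=True)
    os.makedirs(args.results_dir, exist_ok=True)
    config, truth = sim.make_default_scenario(n_pets=args.n_pets, base_seed=args.seed)

    for cond in (1, 2):
        for rep in range(config.replicates_per_condition):
            pets = sim.simulate_pets(config, cond, rep)
            path = os.path.join(args.data_dir, f"{pets.sample_id}.pairs")
            contacts.write_pairs(pets, path)
            print(f"wrote {len(pets)} PETs -> {path}")

    pd.DataFrame(
        [(config.chrom_name, t.start, t.end, f"tad_{i}") for i, t in enumerate(config.tads)]
    ).to_csv(os.path.join(args.results_dir, "tads.bed"), sep="\t", header=False, index=False)
    pd.DataFrame(
        [
            (config.chrom_name, lp.anchor1, lp.anchor1 + 1, f"vp_{i}")
            for i, lp in enumerate(config.loops)
        ]
    ).to_csv(os.path.join(args.results_dir, "viewpoints.bed"), sep="\t", header=False, index=False)
    with open(os.path.join(args.results_dir, "ground_truth.json"), "w") as fh:
        json.dump(
            {
                "chrom": config.chrom_name,
                "chrom_length": config.chrom_length,
                "seed": args.seed,
                "n_pets": args.n_pets,
                "flipped_blocks": [list(x) for x in truth.flipped_blocks],
                "weakened_tads": [list(x) for x in truth.weakened_tads],
                "perturbed_loops": [list(x) for x in truth.perturbed_loops],
            },
            fh,
            indent=2,
        )
    print(f"ground truth: {len(truth.flipped_blocks)} flipped blocks, "
          f"{len(truth.weakened_tads)} weakened TADs, {len(truth.perturbed_loops)} weakened loops")


if __name__ == "__main__":
    main()
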