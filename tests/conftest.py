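import functools

import numpy as np
import pytest

from petdiff import sim


@pytest.fixture(scope="session")
def scenario_cache():
    """Memoized default-scenario simulations shared across test modules.

    Returns a callable (seed, n_pets) -> (config, truth, petsets) where
    petsets maps (condition, replicate) to a PETSet. Caching keeps the
    suite runtime dominated by a handful of unique simulations.
    """

    @functools.lru_cache(maxsize=8)
    def get(seed: int, n_pets: int = 1_000_000):
        config, truth = sim.make_default_scenario(n_pets=n_pets, base_seed=seed)
        petsets = {
            (cond, rep): sim.simulate_pets(config, cond, rep)
            for cond in (1, 2)
            for rep in range(config.replicates_per_condition)
        }
        return config, truth, petsets

    return get


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def loops_only_config(
    loops, n_pets=1_000_000, chrom_length=10_000_000, base_seed=7, alpha=1.0
) -> sim.SimConfig:
    """A featureless single-compartment chromosome plus the given loops."""
    return sim.SimConfig(
        chrom_name="chrT",
        chrom_length=chrom_length,
        n_pets=n_pets,
        decay_exponent=alpha,
        compartment_blocks=(sim.Block(0, chrom_length, "A"),),
        same_compartment_weight=1.0,
        loops=tuple(loops),
        base_seed=base_seed,
    )
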