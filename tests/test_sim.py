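"""Synthetic generator: determinism, decay law, enrichment effects, peak counts."""

import numpy as np
import pytest
from scipy import stats

from petdiff import sim
from petdiff.sim import (
    Block,
    Loop,
    SimConfig,
    Tad,
    make_default_scenario,
    power_law_cdf,
    simulate_peak_counts,
    simulate_pets,
)

from conftest import loops_only_config


def _plain_config(n_pets, alpha=1.0, length=10_000_000, seed=11, **kw):
    return SimConfig(
        chrom_name="chrT",
        chrom_length=length,
        n_pets=n_pets,
        decay_exponent=alpha,
        compartment_blocks=(Block(0, length, "A"),),
        same_compartment_weight=1.0,
        base_seed=seed,
        **kw,
    )


class TestSimulatePets:
    def test_seeded_determinism_byte_identical(self):
        cfg = _plain_config(20_000)
        a = simulate_pets(cfg, 1, 0)
        b = simulate_pets(cfg, 1, 0)
        np.testing.assert_array_equal(a.pos1, b.pos1)
        np.testing.assert_array_equal(a.pos2, b.pos2)

    def test_replicates_and_conditions_differ(self):
        cfg = _plain_config(20_000)
        a = simulate_pets(cfg, 1, 0)
        b = simulate_pets(cfg, 1, 1)
        c = simulate_pets(cfg, 2, 0)
        assert not np.array_equal(a.pos1, b.pos1)
        assert not np.array_equal(a.pos1, c.pos1)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_tad_enrichment_raises_intra_fraction(self, seed):
        tad = (Tad(2_000_000, 2_500_000, enrichment=5.0),)
        flat = (Tad(2_000_000, 2_500_000, enrichment=1.0),)
        frac = {}
        for name, tads in (("enriched", tad), ("flat", flat)):
            cfg = _plain_config(100_000, seed=seed, tads=tads)
            p = simulate_pets(cfg, 1, 0)
            inside = (
                (p.pos1 >= 2_000_000) & (p.pos1 < 2_500_000)
                & (p.pos2 >= 2_000_000) & (p.pos2 < 2_500_000)
            )
            frac[name] = inside.mean()
        assert frac["enriched"] > frac["flat"]

    def test_distance_law_matches_closed_form_cdf(self):
        # alpha = 1, no compartments/TADs/loops: empirical distances follow
        # the truncated power law (KS distance < 0.02 at 1e6 PETs)
        cfg = _plain_config(1_000_000)
        p = simulate_pets(cfg, 1, 0)
        d = np.sort((p.pos2 - p.pos1).astype(float))
        model = power_law_cdf(d, 1.0, cfg.min_distance, cfg.chrom_length - 1)
        emp_hi = np.arange(1, len(d) + 1) / len(d)
        emp_lo = np.arange(0, len(d)) / len(d)
        ks = max(np.abs(emp_hi - model).max(), np.abs(emp_lo - model).max())
        assert ks < 0.02

    def test_same_compartment_weight_enriches_checkerboard(self):
        blocks = tuple(
            Block(i * 1_000_000, (i + 1) * 1_000_000, "A" if i % 2 == 0 else "B")
            for i in range(10)
        )
        cfg = SimConfig(
            chrom_name="chrT",
            chrom_length=10_000_000,
            n_pets=100_000,
            decay_exponent=1.0,
            compartment_blocks=blocks,
            same_compartment_weight=3.0,
            base_seed=5,
        )
        p = simulate_pets(cfg, 1, 0)
        lab1 = (p.pos1 // 1_000_000) % 2
        lab2 = (p.pos2 // 1_000_000) % 2
        far = (p.pos2 - p.pos1) > 1_500_000  # beyond one block => labels informative
        same = (lab1 == lab2)[far].mean()
        assert same > 0.6

    def test_acceptance_guard_aborts_on_pathological_weights(self):
        cfg = _plain_config(
            50_000, loops=(Loop(1_000_000, 1_050_000, strength=2e5, width=100),)
        )
        with pytest.raises(RuntimeError, match="acceptance rate"):
            simulate_pets(cfg, 1, 0)

    def test_replicate_index_validated(self):
        cfg = _plain_config(1000)
        with pytest.raises(ValueError, match="replicate"):
            simulate_pets(cfg, 1, 5)


class TestConfigValidation:
    def test_blocks_must_tile(self):
        with pytest.raises(ValueError, match="tile"):
            SimConfig(
                chrom_name="c",
                chrom_length=100,
                n_pets=10,
                decay_exponent=1.0,
                compartment_blocks=(Block(0, 50, "A"), Block(60, 100, "B")),
                same_compartment_weight=1.0,
            )

    def test_overlapping_tads_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            _plain_config(10, tads=(Tad(0, 100_000), Tad(50_000, 200_000)))

    def test_nonpositive_factors_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            _plain_config(10, tads=(Tad(0, 100_000, enrichment=0.0),))
        with pytest.raises(ValueError):
            _plain_config(0)


class TestPeakCounts:
    def test_zero_diff_fraction_all_shared(self):
        t = simulate_peak_counts(100, 1e6, 0.0, 4.0, seed=1)
        assert set(t.truth) == {"shared"}

    def test_fixed_seed_reproducible(self):
        a = simulate_peak_counts(200, 1e6, 0.2, 3.0, seed=42)
        b = simulate_peak_counts(200, 1e6, 0.2, 3.0, seed=42)
        assert a.counts.equals(b.counts)
        np.testing.assert_array_equal(a.truth, b.truth)

    def test_unit_fold_change_distributionally_null(self):
        # fold change 1 with diff_fraction 0.5: condition labels carry no signal
        t = simulate_peak_counts(10_000, 1e7, 0.5, 1.0, seed=3)
        conds = np.asarray(t.conditions)
        m1 = t.counts.to_numpy()[:, conds == 1].mean(axis=1)
        m2 = t.counts.to_numpy()[:, conds == 2].mean(axis=1)
        assert stats.ks_2samp(m1, m2).pvalue > 0.01

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            simulate_peak_counts(10, 0, 0.1, 2.0, seed=1)

    def test_half_up_half_down(self):
        t = simulate_peak_counts(1000, 1e6, 0.2, 4.0, seed=5)
        assert abs((t.truth == "condition2_up").sum() - (t.truth == "condition2_down").sum()) <= 1


class TestDefaultScenario:
    def test_blocks_tile_chromosome(self):
        config, _ = make_default_scenario(n_pets=1000)
        assert config.compartment_blocks[0].start == 0
        assert config.compartment_blocks[-1].end == config.chrom_length
        for a, b in zip(config.compartment_blocks, config.compartment_blocks[1:]):
            assert a.end == b.start

    def test_edit_lists_sizes(self):
        config, truth = make_default_scenario(n_pets=1000)
        assert len(truth.flipped_blocks) == 10
        assert len(truth.weakened_tads) == 10
        assert len(truth.perturbed_loops) == 10

    def test_reinvocation_identical(self):
        a, ta = make_default_scenario(n_pets=1000)
        b, tb = make_default_scenario(n_pets=1000)
        assert a == b and ta == tb

    def test_tads_at_least_three_analysis_bins(self):
        config, _ = make_default_scenario(n_pets=1000)
        assert len(config.tads) == 100
        assert min(t.end - t.start for t in config.tads) >= 3 * 100_000

    def test_loops_fit_viewpoint_background(self):
        config, _ = make_default_scenario(n_pets=1000)
        assert len(config.loops) == 50
        assert all(lp.anchor2 - lp.anchor1 <= 100_000 for lp in config.loops)

    def test_condition2_view_applies_edits(self):
        config, truth = make_default_scenario(n_pets=1000)
        blocks1, tads1, loops1 = config.condition_view(1)
        blocks2, tads2, loops2 = config.condition_view(2)
        flipped = sum(b1.label != b2.label for b1, b2 in zip(blocks1, blocks2))
        assert flipped == 10
        weakened = [t2 for t1, t2 in zip(tads1, tads2) if t2.enrichment < t1.enrichment]
        assert len(weakened) == 10
        assert all(t.enrichment == 1.0 for t in weakened)  # 2.0 scaled x0.5


class TestLoopMassScaling:
    def test_loop_pet_count_scales_with_strength(self):
        counts = {}
        for s in (1.0, 10.0):
            cfg = loops_only_config(
                [Loop(2_000_000, 2_050_000, strength=s, width=5000)], n_pets=300_000
            )
            p = simulate_pets(cfg, 1, 0)
            hit = (np.abs(p.pos1 - 2_000_000) <= 5000) & (np.abs(p.pos2 - 2_050_000) <= 5000)
            counts[s] = hit.sum()
        assert counts[10.0] > 3 * max(counts[1.0], 1)
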