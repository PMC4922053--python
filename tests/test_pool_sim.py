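"""Synthetic-data generators: diploid genomes, clone pools, reads, misjoins."""

import math

import numpy as np
import pytest

from asmrefine.pool_sim import (
    ClonePool,
    LibrarySpec,
    inject_misjoins,
    lift_pairs,
    lw_covered_fraction,
    pool_stats,
    random_sequence,
    simulate_diploid,
    simulate_pool,
    simulate_reads,
)
from asmrefine.seqio import revcomp


class TestSimulateDiploid:
    def test_zero_het_rate_gives_identical_haplotypes(self):
        g = simulate_diploid(5000, 0.0, seed=1)
        assert g.hap_a == g.hap_b and g.het_sites == []

    def test_het_site_count_binomial(self):
        g = simulate_diploid(100_000, 0.01, seed=2)
        mean, sd = 1000, math.sqrt(100_000 * 0.01 * 0.99)
        assert abs(len(g.het_sites) - mean) < 3 * sd
        # truth table is exact
        for pos, a, b in g.het_sites[:100]:
            assert g.hap_a[pos] == a and g.hap_b[pos] == b and a != b
        assert len(g.hap_a) == len(g.hap_b)

    def test_seed_determinism(self):
        a = simulate_diploid(20_000, 0.02, repeat_fraction=0.1, seed=7)
        b = simulate_diploid(20_000, 0.02, repeat_fraction=0.1, seed=7)
        assert a.hap_a == b.hap_a and a.hap_b == b.hap_b
        assert a.het_sites == b.het_sites and a.repeats == b.repeats

    def test_repeat_fraction_materialized(self):
        g = simulate_diploid(100_000, 0.0, repeat_fraction=0.1, seed=3)
        covered = sum(e - s for s, e in g.repeats)
        assert covered >= 0.08 * 100_000

    @pytest.mark.parametrize("kwargs", [
        {"length": 500, "het_rate": 0.01},
        {"length": 5000, "het_rate": 0.5},
        {"length": 5000, "het_rate": 0.01, "repeat_fraction": 1.5},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            simulate_diploid(**{"seed": 0, **kwargs})


class TestPoolStats:
    def test_hand_computed_two_clone_example(self):
        pool = ClonePool(1000, [(0, 0, 100), (0, 50, 100)], 100, 0)
        st = pool_stats(pool)
        assert st.covered_fraction == pytest.approx(0.15)
        assert st.overlapped_base_fraction == pytest.approx(0.5)
        assert st.redundant_base_fraction == pytest.approx(0.25)

    def test_disjoint_clones_have_no_overlap(self):
        pool = ClonePool(1000, [(0, 0, 100), (0, 500, 100)], 100, 0)
        st = pool_stats(pool)
        assert st.overlapped_base_fraction == 0.0
        assert st.redundant_base_fraction == 0.0
        assert st.covered_fraction == pytest.approx(0.2)

    def test_empty_pool_all_zero(self):
        st = pool_stats(ClonePool(1000, [], 100, 0))
        assert (st.covered_fraction, st.overlapped_base_fraction,
                st.redundant_base_fraction, st.cross_hap_fraction) == (0, 0, 0, 0)

    def test_sweep_agrees_with_per_base_depth_oracle(self):
        G = 100_000
        pool = simulate_pool(G, 60, insert_mean=2000, insert_sd=300, seed=9)
        st = pool_stats(pool)
        depth = np.zeros(G, dtype=int)
        for _, s, L in pool.clones:
            depth[s:s + L] += 1
        total = depth.sum()
        assert st.covered_fraction == pytest.approx((depth > 0).mean())
        assert st.overlapped_base_fraction == \
            pytest.approx(depth[depth >= 2].sum() / total)
        assert st.redundant_base_fraction == \
            pytest.approx((depth[depth > 0] - 1).sum() / total)

    def test_cross_hap_fraction_near_half_for_sparse_diploid_pools(self):
        # sparse clone coverage (c << 1): overlaps are mostly two clones
        # deep, and with uniform haplotype choice half of those mix alleles
        G = 50_000_000
        pool = simulate_pool(G, 10_000, insert_mean=2000, insert_sd=200,
                             diploid=True, seed=10)
        st = pool_stats(pool)
        assert 0.45 < st.cross_hap_fraction < 0.60

    def test_lander_waterman_agreement(self):
        G, n, L = 10_000_000, 2000, 5000
        covs = []
        for seed in range(8):
            pool = simulate_pool(G, n, insert_mean=L, insert_sd=1, seed=seed)
            covs.append(pool_stats(pool).covered_fraction)
        expected = lw_covered_fraction(n, L, G)
        mc_sigma = np.std(covs) / math.sqrt(len(covs)) + 1e-4
        assert abs(np.mean(covs) - expected) < 3 * mc_sigma + 0.002

    def test_lw_formula_values(self):
        assert lw_covered_fraction(0, 36_700, 1.38e9) == 0.0
        assert lw_covered_fraction(1600, 36_700, 1.38e9) == \
            pytest.approx(1 - math.exp(-1600 * 36_700 / 1.38e9))
        with pytest.raises(ValueError):
            lw_covered_fraction(10, 100, 0)


class TestSimulateReads:
    def test_error_free_reads_are_exact_substrings(self, rng):
        genome = {"g": random_sequence(20_000, rng)}
        spec = LibrarySpec(insert_mean=700, insert_sd=50)
        reads, truth = simulate_reads(genome, spec, 200, seed=11)
        for (name, m1, m2), t in zip(reads, truth):
            assert genome["g"][t.pos_a:t.end_a] == m1       # FR mate 1 forward
            assert genome["g"][t.pos_b:t.end_b] == revcomp(m2)

    def test_mate_pair_orientation_is_rf(self, rng):
        genome = {"g": random_sequence(30_000, rng)}
        spec = LibrarySpec(library_type="mp", insert_mean=3000, insert_sd=200)
        _, truth = simulate_reads(genome, spec, 50, seed=12)
        assert all(t.strand_a == "-" and t.strand_b == "+" for t in truth)

    def test_bimodal_mixture_recovered_downstream(self):
        from asmrefine.insert_stats import (detect_modes,
                                            estimate_insert_distribution)
        genome = {"g": random_sequence(60_000, np.random.default_rng(13))}
        spec = LibrarySpec(insert_mean=725, insert_sd=60,
                           minor_insert_mean=300, minor_insert_sd=30,
                           minor_fraction=0.2)
        _, truth = simulate_reads(genome, spec, 4000, seed=14)
        modes = detect_modes(estimate_insert_distribution(truth))
        assert abs(modes.main_peak - 725) <= 30
        assert modes.minor_peak is not None
        assert abs(modes.minor_peak - 300) <= 30

    def test_zero_reads_give_empty_outputs(self):
        reads, truth = simulate_reads({"g": "ACGT" * 1000},
                                      LibrarySpec(insert_mean=500, insert_sd=10),
                                      0, seed=0)
        assert reads == [] and truth == []

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValueError):
            LibrarySpec(insert_mean=100, insert_sd=10, read_len=150)


class TestInjectMisjoins:
    def test_zero_events_is_identity(self, rng):
        asm = {"a": random_sequence(5000, rng), "b": random_sequence(5000, rng)}
        res = inject_misjoins(asm, 0, seed=1)
        assert res.assembly == asm and res.junctions == []

    def test_single_event_makes_two_chimeras(self, rng):
        asm = {"a": random_sequence(5000, rng), "b": random_sequence(5000, rng)}
        res = inject_misjoins(asm, 1, seed=2)
        assert len(res.junctions) == 2
        # total sequence is conserved
        assert sum(map(len, res.assembly.values())) == 10_000
        # each output scaffold is a two-part chimera: content around the
        # junction comes from different originals
        for name, pos in res.junctions:
            seq = res.assembly[name]
            left, right = seq[pos - 50:pos], seq[pos:pos + 50]
            origin = {left in s for s in asm.values()}
            assert any(left in s and right not in s for s in asm.values())

    def test_lifted_pairs_preserve_sequence_content(self, rng):
        asm = {f"s{i}": random_sequence(20_000, rng) for i in range(3)}
        spec = LibrarySpec(insert_mean=600, insert_sd=40)
        _, truth = simulate_reads(asm, spec, 300, seed=3)
        res = inject_misjoins(asm, 2, seed=4)
        lifted = lift_pairs(truth, res.block_map)
        assert 0 < len(lifted) <= len(truth)
        by_id = {p.read_id: p for p in truth}
        for lp in lifted[:100]:
            tp = by_id[lp.read_id]
            assert res.assembly[lp.scaffold_a][lp.pos_a:lp.end_a] == \
                asm[tp.scaffold_a][tp.pos_a:tp.end_a]

    def test_too_few_scaffolds_rejected(self):
        with pytest.raises(ValueError):
            inject_misjoins({"only": "A" * 10_000}, 1, seed=0)


def test_simulate_pool_requires_feasible_insert():
    with pytest.raises(ValueError):
        simulate_pool(10_000, 5, insert_mean=20_000, seed=0)
    pool = simulate_pool(1_000_000, 0, seed=0)
    assert pool.n_clones == 0
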