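"""Overlap detection, graph merging, tip absorption, haplotype collapse."""

import numpy as np
import pytest

from asmrefine.asm_merge import (
    Link,
    collapse_haplotypes,
    find_overlaps,
    merge_pipeline,
    merge_round,
    tip_merge,
)
from asmrefine.errors import InputError
from asmrefine.pool_sim import (
    clone_sequences,
    random_sequence,
    simulate_diploid,
    simulate_pool,
)
from asmrefine.seqio import revcomp

from conftest import n50


def _mutate(seq, n_sites, rng):
    arr = list(seq)
    for p in rng.choice(len(arr), size=n_sites, replace=False):
        arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
    return "".join(arr)


def shift_enumeration_overlaps(contigs, min_overlap, max_divergence):
    """Exhaustive independent oracle: every diagonal of every pair, both
    orientations, via FFT cross-correlation match counting.

    Exact for substitution-only divergence (Hamming distance along the
    diagonal equals edit distance for the constructions used here).
    Returns {(a, b, strand)} for pairs with a qualifying end-anchored
    overlap.
    """
    from scipy.signal import fftconvolve

    names = sorted(contigs)
    found = set()

    def onehot(seq):
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        return [(arr == ord(c)).astype(float) for c in "ACGT"]

    for i, na in enumerate(names):
        a = contigs[na]
        ha = onehot(a)
        for nb in names[i + 1:]:
            b = contigs[nb]
            for strand, bseq in (("same", b), ("opposite", revcomp(b))):
                hb = onehot(bseq)
                # matches[s] = number of agreeing bases when b is shifted
                # by s relative to a
                corr = sum(fftconvolve(xa, xb[::-1]) for xa, xb in zip(ha, hb))
                matches = np.rint(corr).astype(int)
                for idx, m in enumerate(matches):
                    shift = idx - (len(bseq) - 1)
                    olen = min(len(a), shift + len(bseq)) - max(0, shift)
                    if olen < min_overlap:
                        continue
                    if (olen - m) / olen <= max_divergence:
                        found.add((na, nb, strand))
                        break
    return found


class TestFindOverlaps:
    def test_exact_construction(self, rng):
        S = random_sequence(9000, rng)
        ovls = find_overlaps({"A": S[:6000], "B": S[3000:9000]}, 2400, 0.015)
        assert len(ovls) == 1
        o = ovls[0]
        assert (o.length, o.edit_distance, o.strand) == (3000, 0, "same")
        assert (o.a_start, o.a_end, o.b_start, o.b_end) == (3000, 6000, 0, 3000)

    def test_reverse_complement_overlap(self, rng):
        S = random_sequence(9000, rng)
        ovls = find_overlaps({"A": S[:6000], "B": revcomp(S[3000:9000])},
                             2400, 0.015)
        assert len(ovls) == 1
        assert ovls[0].strand == "opposite"
        assert ovls[0].length == 3000

    def test_divergence_threshold(self, rng):
        S = random_sequence(9000, rng)
        A, B = S[:6000], S[3000:9000]
        B = _mutate(B[:3000], 30, rng) + B[3000:]  # 1 % over the overlap
        hit = find_overlaps({"A": A, "B": B}, 2400, 0.015)
        assert len(hit) == 1
        assert hit[0].divergence == pytest.approx(0.01, abs=0.002)
        assert find_overlaps({"A": A, "B": B}, 2400, 0.005) == []

    def test_duplicate_names_rejected(self):
        with pytest.raises(InputError):
            find_overlaps([("c", "A" * 100), ("c", "C" * 100)], 50, 0.1)

    def test_agrees_with_shift_enumeration_oracle(self, rng):
        # mixed case: disjoint random contigs plus true overlap pairs
        contigs = {f"r{i}": random_sequence(1500, rng) for i in range(8)}
        S1, S2 = random_sequence(2500, rng), random_sequence(2500, rng)
        contigs["o1a"], contigs["o1b"] = S1[:1500], S1[700:2500]
        contigs["o2a"], contigs["o2b"] = S2[:1500], revcomp(S2[700:2500])
        min_ov, max_div = 500, 0.015
        mine = {(o.contig_a, o.contig_b, o.strand)
                for o in find_overlaps(contigs, min_ov, max_div)}
        oracle = shift_enumeration_overlaps(contigs, min_ov, max_div)
        assert mine == oracle
        assert ("o1a", "o1b", "same") in mine
        assert ("o2a", "o2b", "opposite") in mine


class TestMergeRound:
    def test_identical_copies_collapse_to_one(self, rng):
        S = random_sequence(5000, rng)
        contigs = {"x": S, "y": S}
        merged, _ = merge_round(contigs, find_overlaps(contigs, 2400, 0.015))
        assert len(merged) == 1
        assert next(iter(merged.values())) == S

    def test_three_tile_exact_reconstruction(self, rng):
        S = random_sequence(20_000, rng)
        tiles = {"c1": S[:8000], "c2": S[5000:14_000], "c3": S[11_000:]}
        merged, _ = merge_round(tiles, find_overlaps(tiles, 2400, 0.015))
        assert len(merged) == 1
        assert next(iter(merged.values())) == S

    def test_repeat_resolved_only_with_link_support(self, rng):
        # X-R, R-Y and R'-Z where R' == R (5 kb repeat); links assert X-R-Y
        R = random_sequence(5000, rng)
        X = random_sequence(4000, rng) + R[:3000]
        Y = R[2000:] + random_sequence(4000, rng)
        Z = R[2000:] + random_sequence(4000, rng)
        contigs = {"X": X, "R": R, "Rp": R, "Y": Y, "Z": Z}
        links = [Link("X", 0, "R", 0), Link("R", 0, "Y", 0)]
        overlaps = find_overlaps(contigs, 2400, 0.015)
        merged, _ = merge_round(contigs, overlaps, links=links)
        seqs = set(merged.values())
        assert X[:4000] + R + Y[3000:] in seqs  # X || R || Y
        assert Z in seqs  # unsupported branch stays separate

        # without links the branch at R is ambiguous: no chimeric join
        merged_nolink, _ = merge_round(contigs, overlaps)
        assert all(X[:4000] + R + Y[3000:] != s for s in merged_nolink.values())


class TestTipMerge:
    def test_contained_end_tip_absorbed(self, rng):
        big = random_sequence(10_000, rng)
        contigs = {"big": big, "tip": big[-300:]}
        overlaps = find_overlaps(contigs, 250, 0.02)
        merged = tip_merge(contigs, overlaps, 250)
        assert merged == {"big": big}

    def test_below_threshold_tip_kept(self, rng):
        big = random_sequence(10_000, rng)
        contigs = {"big": big, "tip": big[-200:]}
        overlaps = find_overlaps(contigs, 150, 0.02)
        merged = tip_merge(contigs, overlaps, 250)
        assert set(merged) == {"big", "tip"}

    def test_dovetail_tip_extends_partner(self, rng):
        S = random_sequence(10_500, rng)
        contigs = {"big": S[:10_000], "tip": S[9_600:]}  # 400 bp overlap
        overlaps = find_overlaps(contigs, 250, 0.02)
        merged = tip_merge(contigs, overlaps, 250)
        assert set(merged) == {"big"}
        assert merged["big"] == S

    def test_interior_nodes_untouched(self, rng):
        S = random_sequence(30_000, rng)
        contigs = {"c1": S[:12_000], "c2": S[8_000:22_000], "c3": S[18_000:],
                   "tip": S[29_600:]}
        overlaps = find_overlaps(contigs, 250, 0.02)
        merged = tip_merge(contigs, overlaps, 250)
        # interior (multi-neighbour) nodes survive under their own names;
        # the short terminal tip is absorbed
        assert {"c2", "c3"} <= set(merged)
        assert "tip" not in merged


class TestCollapseHaplotypes:
    def test_divergent_haplotype_pair_collapses(self):
        g = simulate_diploid(10_000, 0.01, seed=3)
        col = collapse_haplotypes({"h1": g.hap_a, "h2": g.hap_b}, 4000, 0.03)
        assert len(col) == 1
        assert len(next(iter(col.values()))) == 10_000

    def test_highly_divergent_pair_kept_apart(self):
        g = simulate_diploid(10_000, 0.05, seed=4)
        col = collapse_haplotypes({"h1": g.hap_a, "h2": g.hap_b}, 4000, 0.03)
        assert len(col) == 2

    def test_total_length_never_increases(self, rng):
        g = simulate_diploid(60_000, 0.01, seed=5)
        asm = {}
        for hi, hap in enumerate((g.hap_a, g.hap_b)):
            for j in range(0, 55_000, 10_000):
                asm[f"h{hi}t{j}"] = hap[j:j + 15_000]
        before = sum(len(s) for s in asm.values())
        col = collapse_haplotypes(asm, 4000, 0.03)
        after = sum(len(s) for s in col.values())
        assert after <= before
        # diploid tiling collapses to roughly the haploid length
        assert 60_000 * 0.9 <= after <= 60_000 * 1.1


class TestMergePipeline:
    def test_single_assembly_without_self_overlap_is_identity(self, rng):
        asm = {f"c{i}": random_sequence(3000, rng) for i in range(5)}
        assert merge_pipeline([asm]) == asm

    def test_subset_assembly_absorbed_by_superset(self, rng):
        sup = {f"c{i}": random_sequence(5000, rng) for i in range(4)}
        sub = {"c0": sup["c0"], "c2": sup["c2"]}
        merged = merge_pipeline([sup, sub])
        assert sorted(merged.values()) == sorted(sup.values())

    def test_pool_tiling_reconstruction_and_idempotence(self):
        G = 200_000
        genome = simulate_diploid(G, 0.0, seed=6)
        assemblies = [
            clone_sequences(
                simulate_pool(G, 3, insert_mean=8000, insert_sd=800, seed=700 + p),
                genome)
            for p in range(40)
        ]
        merged = merge_pipeline(assemblies)
        total = sum(len(s) for s in merged.values())
        assert abs(total - G) / G < 0.10
        in_lens = [len(s) for a in assemblies for s in a.values()]
        assert n50([len(s) for s in merged.values()]) >= 3 * np.mean(in_lens)
        # idempotence up to naming
        again = merge_pipeline([merged])
        assert sorted(len(s) for s in again.values()) == \
            sorted(len(s) for s in merged.values())

    def test_coherent_links_reinserted_as_gapped_scaffold(self, rng):
        a = {"u": random_sequence(3000, rng), "v": random_sequence(3000, rng)}
        links = [Link("u", 0, "v", 0, gap=50)]
        merged = merge_pipeline([a], links=links)
        assert len(merged) == 1
        seq = next(iter(merged.values()))
        assert seq == a["u"] + "N" * 50 + a["v"]
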