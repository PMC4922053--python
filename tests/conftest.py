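"""Shared fixtures and oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from asmrefine.pool_sim import random_sequence
from asmrefine.seqio import revcomp


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_817)


def brute_force_canonical_count(reads, k):
    """Independent dict-based canonical k-mer counter."""
    counts: dict[str, int] = {}
    for read in reads:
        for i in range(len(read) - k + 1):
            kmer = read[i:i + k]
            if set(kmer) - set("ACGT"):
                continue
            canon = min(kmer, revcomp(kmer))
            counts[canon] = counts.get(canon, 0) + 1
    return counts


def spectrum_from_counts(counts):
    hist: dict[int, int] = {}
    for c in counts.values():
        hist[c] = hist.get(c, 0) + 1
    return hist


def simulate_uniform_reads(genome: str, depth: float, read_len: int,
                           seed: int) -> list[str]:
    gen = np.random.default_rng(seed)
    n = int(depth * len(genome) / read_len)
    starts = gen.integers(0, len(genome) - read_len, size=n)
    return [genome[s:s + read_len] for s in starts]


def n50(lengths) -> int:
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for L in ordered:
        acc += L
        if acc >= half:
            return L
    return 0


def make_sam(path, records, refs=(("ref", 100_000),)):
    """Write a minimal SAM file from (qname, flag, rname, pos1, mapq, cigar,
    rnext, pnext, tlen, seq, tags) tuples."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\n")
        for name, length in refs:
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for rec in records:
            qname, flag, rname, pos1, mapq, cigar, rnext, pnext, tlen, seq = rec[:10]
            tags = rec[10] if len(rec) > 10 else []
            fields = [qname, str(flag), rname, str(pos1), str(mapq), cigar,
                      rnext, str(pnext), str(tlen), seq, "*"] + list(tags)
            fh.write("\t".join(fields) + "\n")
    return path


__all__ = [
    "brute_force_canonical_count", "spectrum_from_counts",
    "simulate_uniform_reads", "n50", "make_sam", "random_sequence",
]
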