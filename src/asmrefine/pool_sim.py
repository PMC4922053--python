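"""Synthetic diploid genomes, clone pools, read libraries, and misjoins.

This module generates every input class the refinement pipeline consumes:
diploid genomes with configurable heterozygosity and repeat content, pools
of large-insert clones with Lander-Waterman overlap statistics, paired-end
and mate-pair read libraries with optional bimodal insert contamination,
and assemblies with injected misjoins plus truth breakpoints.  All
generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .insert_stats import PairAlignment
from .seqio import revcomp

__all__ = [
    "DiploidGenome",
    "ClonePool",
    "PoolStats",
    "LibrarySpec",
    "MisjoinResult",
    "simulate_diploid",
    "simulate_pool",
    "pool_stats",
    "lw_covered_fraction",
    "simulate_reads",
    "inject_misjoins",
    "lift_pairs",
    "clone_sequences",
    "random_sequence",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


@dataclass
class DiploidGenome:
    """Two haplotypes differing at an exact table of substitution sites."""

    hap_a: str
    hap_b: str
    het_sites: list[tuple[int, str, str]]  # (pos, allele_a, allele_b)
    repeats: list[tuple[int, int]] = field(default_factory=list)
    seed: int = 0

    @property
    def length(self) -> int:
        return len(self.hap_a)


@dataclass
class ClonePool:
    """Clones as (haplotype, start, length) intervals on a genome of size G."""

    genome_length: int
    clones: list[tuple[int, int, int]]
    insert_mean: float
    insert_sd: float
    seed: int = 0

    @property
    def n_clones(self) -> int:
        return len(self.clones)


@dataclass
class PoolStats:
    covered_fraction: float
    overlapped_base_fraction: float
    redundant_base_fraction: float
    cross_hap_fraction: float


def simulate_diploid(
    length: int,
    het_rate: float,
    repeat_fraction: float = 0.0,
    seed: int = 0,
) -> DiploidGenome:
    """Simulate a diploid genome with substitution heterozygosity.

    Haplotype B equals haplotype A with substitutions at Bernoulli
    (``het_rate``) sites; ``repeat_fraction`` of the length is overwritten
    with tandem copies of a single repeat-family segment before the
    haplotypes are derived, so both haplotypes share the repeat structure.
    """
    if not 0.0 <= het_rate <= 0.2:
        raise ValueError("het_rate must lie in [0, 0.2]")
    if not 0.0 <= repeat_fraction < 1.0:
        raise ValueError("repeat_fraction must lie in [0, 1)")
    if length < 1000:
        raise ValueError("length must be >= 1 kb")
    rng = np.random.default_rng(seed)
    base = np.frombuffer(random_sequence(length, rng).encode(), dtype=np.uint8).copy()

    repeats: list[tuple[int, int]] = []
    if repeat_fraction > 0:
        unit_len = min(2000, max(200, length // 20))
        unit_start = int(rng.integers(0, length - unit_len))
        unit = base[unit_start:unit_start + unit_len].copy()
        target = int(repeat_fraction * length)
        placed = 0
        taken: list[tuple[int, int]] = [(unit_start, unit_start + unit_len)]
        attempts = 0
        while placed < target and attempts < 10_000:
            attempts += 1
            s = int(rng.integers(0, length - unit_len))
            if any(s < e0 and s + unit_len > s0 for s0, e0 in taken):
                continue
            base[s:s + unit_len] = unit
            taken.append((s, s + unit_len))
            repeats.append((s, s + unit_len))
            placed += unit_len

    hap_a = base.tobytes().decode()
    hap_b_arr = base.copy()
    sites = np.flatnonzero(rng.random(length) < het_rate)
    het_sites: list[tuple[int, str, str]] = []
    for pos in sites:
        old = hap_b_arr[pos]
        choices = _BASES[_BASES != old]
        new = choices[int(rng.integers(0, 3))]
        hap_b_arr[pos] = new
        het_sites.append((int(pos), chr(old), chr(new)))
    return DiploidGenome(hap_a=hap_a, hap_b=hap_b_arr.tobytes().decode(),
                         het_sites=het_sites, repeats=repeats, seed=seed)


def simulate_pool(
    genome_length: int,
    n_clones: int,
    insert_mean: float = 36_700.0,
    insert_sd: float = 4_970.0,
    diploid: bool = False,
    seed: int = 0,
) -> ClonePool:
    """Place clones uniformly on a genome with truncated-normal lengths."""
    if n_clones < 0:
        raise ValueError("n_clones must be >= 0")
    if insert_mean >= genome_length:
        raise ValueError("insert_mean must be smaller than the genome")
    rng = np.random.default_rng(seed)
    lengths = np.maximum(
        rng.normal(insert_mean, insert_sd, size=n_clones), 1000.0
    ).astype(np.int64)
    starts = (rng.random(n_clones) * (genome_length - lengths)).astype(np.int64)
    haps = rng.integers(0, 2, size=n_clones) if diploid else np.zeros(n_clones, dtype=int)
    clones = [(int(h), int(s), int(l)) for h, s, l in zip(haps, starts, lengths)]
    return ClonePool(genome_length=genome_length, clones=clones,
                     insert_mean=insert_mean, insert_sd=insert_sd, seed=seed)


def pool_stats(pool: ClonePool) -> PoolStats:
    """Overlap statistics by interval sweep (no per-base arrays).

    covered_fraction: genome fraction at clone depth >= 1.
    overlapped_base_fraction: fraction of clone (sequenced) bases lying at
        positions covered by >= 2 clones.
    redundant_base_fraction: fraction of clone bases that are redundant,
        counting (depth-1)/depth of the bases at depth k — i.e. the excess
        over a single-copy representation.
    cross_hap_fraction: among positions at depth >= 2, the fraction covered
        by clones from both haplotypes.
    """
    if pool.n_clones == 0:
        return PoolStats(0.0, 0.0, 0.0, 0.0)
    events: list[tuple[int, int, int]] = []
    for hap, start, length in pool.clones:
        events.append((start, 1, hap))
        events.append((start + length, -1, hap))
    events.sort()

    covered = 0
    total_clone_bases = 0
    overlapped_clone_bases = 0
    redundant_bases = 0
    depth2_len = 0
    cross_len = 0
    depth = 0
    hap_depth = [0, 0]
    prev = events[0][0]
    for pos, delta, hap in events:
        seg = pos - prev
        if seg > 0 and depth > 0:
            covered += seg
            total_clone_bases += depth * seg
            redundant_bases += (depth - 1) * seg
            if depth >= 2:
                overlapped_clone_bases += depth * seg
                depth2_len += seg
                if hap_depth[0] > 0 and hap_depth[1] > 0:
                    cross_len += seg
        prev = pos
        depth += delta
        hap_depth[hap] += delta

    return PoolStats(
        covered_fraction=covered / pool.genome_length,
        overlapped_base_fraction=overlapped_clone_bases / total_clone_bases,
        redundant_base_fraction=redundant_bases / total_clone_bases,
        cross_hap_fraction=(cross_len / depth2_len) if depth2_len else 0.0,
    )


def lw_covered_fraction(n_clones: int, clone_length: float, genome_length: float) -> float:
    """Lander-Waterman expected covered fraction, 1 - exp(-nL/G)."""
    if genome_length <= 0:
        raise ValueError("genome length must be > 0")
    return 1.0 - math.exp(-n_clones * clone_length / genome_length)


def clone_sequences(pool: ClonePool, genome: DiploidGenome) -> dict[str, str]:
    """Extract clone sequences from their haplotype of origin."""
    haps = (genome.hap_a, genome.hap_b)
    return {
        f"clone_{i}_h{hap}": haps[hap][start:start + length]
        for i, (hap, start, length) in enumerate(pool.clones)
    }


@dataclass
class LibrarySpec:
    """Read-library geometry and noise model.

    ``library_type`` 'pe' emits inward-facing (FR) mates, 'mp' outward
    (RF).  A second insert mode (``minor_*``) models short-insert
    contamination; ``chimera_rate`` models junction artifacts where the two
    mates derive from unrelated loci.
    """

    library_type: str = "pe"
    insert_mean: float = 725.0
    insert_sd: float = 60.0
    read_len: int = 150
    minor_insert_mean: float | None = None
    minor_insert_sd: float | None = None
    minor_fraction: float = 0.0
    error_rate: float = 0.0
    chimera_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.library_type not in ("pe", "mp"):
            raise ValueError("library_type must be 'pe' or 'mp'")
        if self.read_len >= self.insert_mean:
            raise ValueError("read_len must be smaller than insert_mean")

    @property
    def orientation(self) -> str:
        return "fr" if self.library_type == "pe" else "rf"


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    sites = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for pos in sites:
        choices = _BASES[_BASES != arr[pos]]
        arr[pos] = choices[int(rng.integers(0, 3))]
    return arr.tobytes().decode()


def simulate_reads(
    genome: Mapping[str, str] | DiploidGenome,
    spec: LibrarySpec,
    n_pairs: int,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], list[PairAlignment]]:
    """Simulate read pairs with truth alignments.

    Returns ``(reads, truth)`` where reads are (name, mate1, mate2) tuples
    and truth holds the error-free alignment coordinates of every mate on
    the source sequences.  Fragments are drawn from the configured insert
    mixture; scaffolds are sampled proportionally to length.
    """
    if isinstance(genome, DiploidGenome):
        seqs = {"hapA": genome.hap_a, "hapB": genome.hap_b}
    else:
        seqs = dict(genome)
    names = [n for n, s in seqs.items() if len(s) >= spec.insert_mean]
    if not names and n_pairs > 0:
        raise ValueError("no sequence long enough for the requested insert size")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(seqs[n]) for n in names], dtype=float)
    probs = lengths / lengths.sum() if names else None

    reads: list[tuple[str, str, str]] = []
    truth: list[PairAlignment] = []
    rl = spec.read_len
    for i in range(n_pairs):
        name = names[int(rng.choice(len(names), p=probs))]
        seq = seqs[name]
        if spec.minor_fraction > 0 and rng.random() < spec.minor_fraction:
            ins = rng.normal(spec.minor_insert_mean, spec.minor_insert_sd or 1.0)
        else:
            ins = rng.normal(spec.insert_mean, spec.insert_sd)
        ins = int(max(rl + 1, min(round(ins), len(seq))))

        if spec.chimera_rate > 0 and rng.random() < spec.chimera_rate:
            s1 = int(rng.integers(0, len(seq) - rl))
            s2 = int(rng.integers(0, len(seq) - rl))
            frag_a = (s1, s1 + rl)
            frag_b = (s2, s2 + rl)
        else:
            start = int(rng.integers(0, len(seq) - ins + 1))
            frag_a = (start, start + rl)
            frag_b = (start + ins - rl, start + ins)

        left = seq[frag_a[0]:frag_a[1]]
        right = seq[frag_b[0]:frag_b[1]]
        if spec.library_type == "pe":
            m1, m2 = left, revcomp(right)
            strand_a, strand_b = "+", "-"
        else:
            m1, m2 = revcomp(left), right
            strand_a, strand_b = "-", "+"
        rid = f"sim_{i}"
        reads.append((rid, _mutate(m1, spec.error_rate, rng),
                      _mutate(m2, spec.error_rate, rng)))
        truth.append(PairAlignment(
            read_id=rid,
            scaffold_a=name, pos_a=frag_a[0], end_a=frag_a[1], strand_a=strand_a,
            scaffold_b=name, pos_b=frag_b[0], end_b=frag_b[1], strand_b=strand_b,
        ))
    return reads, truth


@dataclass
class MisjoinResult:
    assembly: dict[str, str]
    junctions: list[tuple[str, int]]          # (scaffold, junction position)
    block_map: dict[str, list[tuple[int, int, str, int]]]
    # per original scaffold: sorted (orig_start, orig_end, new_name, new_offset)


def inject_misjoins(
    assembly: Mapping[str, str],
    n_misjoins: int,
    seed: int = 0,
    min_margin: int = 1000,
) -> MisjoinResult:
    """Create chimeric scaffolds by random cut-and-swap events.

    Each event cuts two distinct scaffolds at interior points and swaps
    their tails, producing two chimeras and two truth junctions.  Junction
    coordinates are reported in output coordinates; ``block_map`` lifts
    original coordinates into the misjoined assembly.
    """
    names = list(assembly)
    eligible = [n for n in names if len(assembly[n]) >= 2 * min_margin]
    if n_misjoins > 0 and len(eligible) < 2:
        raise ValueError("need at least two scaffolds long enough to cut")
    rng = np.random.default_rng(seed)

    # each scaffold is a list of (orig_name, orig_start, orig_end) blocks
    blocks: dict[str, list[tuple[str, int, int]]] = {
        n: [(n, 0, len(s))] for n, s in assembly.items()
    }

    def cut(block_list: list[tuple[str, int, int]], pos: int):
        off = 0
        for i, (orig, s, e) in enumerate(block_list):
            if off + (e - s) > pos:
                inner = pos - off
                head = block_list[:i] + ([(orig, s, s + inner)] if inner else [])
                tail = ([(orig, s + inner, e)] if inner < e - s else []) + block_list[i + 1:]
                return head, tail
            off += e - s
        return block_list, []

    for _ in range(n_misjoins):
        a, b = rng.choice(len(eligible), size=2, replace=False)
        na, nb = eligible[int(a)], eligible[int(b)]
        len_a = sum(e - s for _, s, e in blocks[na])
        len_b = sum(e - s for _, s, e in blocks[nb])
        ca = int(rng.integers(min_margin, len_a - min_margin))
        cb = int(rng.integers(min_margin, len_b - min_margin))
        head_a, tail_a = cut(blocks[na], ca)
        head_b, tail_b = cut(blocks[nb], cb)
        blocks[na] = head_a + tail_b
        blocks[nb] = head_b + tail_a

    out: dict[str, str] = {}
    junctions: list[tuple[str, int]] = []
    block_map: dict[str, list[tuple[int, int, str, int]]] = {n: [] for n in names}
    for name, blist in blocks.items():
        parts = []
        off = 0
        prev: tuple[str, int, int] | None = None
        for orig, s, e in blist:
            if prev is not None and (prev[0], prev[2]) != (orig, s):
                junctions.append((name, off))
            parts.append(assembly[orig][s:e])
            block_map[orig].append((s, e, name, off))
            off += e - s
            prev = (orig, s, e)
        out[name] = "".join(parts)
    for orig in block_map:
        block_map[orig].sort()
    return MisjoinResult(assembly=out, junctions=junctions, block_map=block_map)


def lift_pairs(
    truth: list[PairAlignment],
    block_map: dict[str, list[tuple[int, int, str, int]]],
) -> list[PairAlignment]:
    """Lift truth pair coordinates through a misjoin block map.

    Mates fully contained in one block are relocated; pairs with a mate
    straddling a block boundary are dropped (a mapper would clip them).
    """
    starts_per_orig = {n: [b[0] for b in bl] for n, bl in block_map.items()}

    def lift(orig: str, s: int, e: int):
        bl = block_map[orig]
        i = bisect.bisect_right(starts_per_orig[orig], s) - 1
        if i < 0:
            return None
        bs, be, new_name, new_off = bl[i]
        if e > be:
            return None
        return new_name, new_off + (s - bs), new_off + (e - bs)

    lifted = []
    for p in truth:
        la = lift(p.scaffold_a, p.pos_a, p.end_a)
        lb = lift(p.scaffold_b, p.pos_b, p.end_b)
        if la is None or lb is None:
            continue
        lifted.append(PairAlignment(
            read_id=p.read_id,
            scaffold_a=la[0], pos_a=la[1], end_a=la[2], strand_a=p.strand_a,
            scaffold_b=lb[0], pos_b=lb[1], end_b=lb[2], strand_b=p.strand_b,
            mapq_a=p.mapq_a, mapq_b=p.mapq_b,
        ))
    return lifted
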