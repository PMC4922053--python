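"""Insert-size estimation, bimodality detection, and short-insert filtering.

Paired-end libraries occasionally carry a second, shorter insert population
(e.g. from over-fragmentation during library preparation), visible as a
minor mode in the empirical insert-size distribution.  This module
estimates the distribution from pair alignments, detects such modes, and
removes pairs belonging to the short mode when a third ("connecting") read
overlaps both mates — geometric evidence that the true fragment is short.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
from intervaltree import IntervalTree
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .errors import InsufficientDataError

__all__ = [
    "PairAlignment",
    "ReadAlignment",
    "InsertDistribution",
    "ModePair",
    "DedupSpectrum",
    "estimate_insert_distribution",
    "detect_modes",
    "filter_short_insert_pairs",
    "dedup_length_spectrum",
    "read_pairs_from_sam",
    "read_alignments_from_sam",
    "read_pairs_from_tsv",
    "write_pairs_tsv",
]


@dataclass(frozen=True)
class PairAlignment:
    """Alignment coordinates of a read pair (0-based, half-open)."""

    read_id: str
    scaffold_a: str
    pos_a: int
    end_a: int
    strand_a: str
    scaffold_b: str
    pos_b: int
    end_b: int
    strand_b: str
    mapq_a: int = 60
    mapq_b: int = 60

    def __post_init__(self) -> None:
        if self.end_a <= self.pos_a or self.end_b <= self.pos_b:
            raise ValueError("alignment end must exceed start")
        if self.strand_a not in "+-" or self.strand_b not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def same_scaffold(self) -> bool:
        return self.scaffold_a == self.scaffold_b

    @property
    def insert_size(self) -> int:
        """Outer distance spanned by the pair (same-scaffold pairs only)."""
        return max(self.end_a, self.end_b) - min(self.pos_a, self.pos_b)


@dataclass(frozen=True)
class ReadAlignment:
    """A single-read alignment interval."""

    read_id: str
    scaffold: str
    start: int
    end: int


@dataclass
class InsertDistribution:
    """Empirical pair-separation model with mean +/- 3 sigma bounds."""

    hist: dict[int, int]
    mean: float
    sd: float
    expected_orientation: str = "fr"
    sigma_mult: float = 3.0

    @property
    def lo(self) -> float:
        return max(0.0, self.mean - self.sigma_mult * self.sd)

    @property
    def hi(self) -> float:
        return self.mean + self.sigma_mult * self.sd

    def bounds(self, sigma_mult: float) -> tuple[float, float]:
        return (max(0.0, self.mean - sigma_mult * self.sd),
                self.mean + sigma_mult * self.sd)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"mean": self.mean, "sd": self.sd,
                       "expected_orientation": self.expected_orientation,
                       "sigma_mult": self.sigma_mult,
                       "hist": {str(k): v for k, v in self.hist.items()}}, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "InsertDistribution":
        with open(path) as fh:
            d = json.load(fh)
        return cls(hist={int(k): v for k, v in d["hist"].items()},
                   mean=d["mean"], sd=d["sd"],
                   expected_orientation=d.get("expected_orientation", "fr"),
                   sigma_mult=d.get("sigma_mult", 3.0))


@dataclass
class ModePair:
    main_peak: int
    minor_peak: int | None = None
    minor_mass_fraction: float = 0.0


@dataclass
class DedupSpectrum:
    """Length spectrum after depth-threshold deduplication."""

    hist: dict[int, int]
    mean: float
    sd: float


def _orientation_ok(p: PairAlignment, expected: str) -> bool:
    """Check mate orientation against the library convention.

    "fr" (paired-end): the leftmost mate on '+', rightmost on '-';
    "rf" (mate-pair after junction processing): the opposite.
    """
    if p.strand_a == p.strand_b:
        return False
    if p.pos_a <= p.pos_b:
        left_strand = p.strand_a
    else:
        left_strand = p.strand_b
    return left_strand == ("+" if expected == "fr" else "-")


def estimate_insert_distribution(
    pairs: Iterable[PairAlignment],
    min_mapq: int = 20,
    expected_orientation: str = "fr",
    min_pairs: int = 100,
    trim_fraction: float = 0.01,
) -> InsertDistribution:
    """Estimate the insert-size distribution from usable pair alignments.

    Usable pairs map to the same scaffold, in the expected orientation,
    with both mates at or above ``min_mapq``.  The top and bottom
    ``trim_fraction`` of inserts are trimmed before computing mean and sd.
    """
    inserts = [
        p.insert_size
        for p in pairs
        if p.same_scaffold
        and min(p.mapq_a, p.mapq_b) >= min_mapq
        and _orientation_ok(p, expected_orientation)
    ]
    if len(inserts) < min_pairs:
        raise InsufficientDataError(
            f"only {len(inserts)} usable pairs (need >= {min_pairs})")
    arr = np.sort(np.asarray(inserts))
    n_trim = int(len(arr) * trim_fraction)
    trimmed = arr[n_trim : len(arr) - n_trim] if n_trim else arr
    return InsertDistribution(
        hist=dict(Counter(inserts)),
        mean=float(np.mean(trimmed)),
        sd=float(np.std(trimmed)),
        expected_orientation=expected_orientation,
    )


def detect_modes(dist: InsertDistribution, min_separation_frac: float = 0.25,
                 min_prominence_frac: float = 0.02,
                 min_minor_mass: float = 0.05) -> ModePair:
    """Find the main and (if any) minor mode of the insert histogram.

    Local maxima of the smoothed histogram separated by at least
    ``min_separation_frac`` of the main-peak location qualify; the mode
    carrying the larger mass is main (ties broken toward the larger
    location).  A minor mode is reported with its mass fraction when that
    fraction reaches ``min_minor_mass`` (smaller bumps are sampling noise).
    """
    if not dist.hist:
        raise InsufficientDataError("empty insert histogram")
    max_len = max(dist.hist)
    pad = max(3, max_len // 50)
    dense = np.zeros(max_len + 1 + 2 * pad)
    for length, n in dist.hist.items():
        dense[length + pad] = n
    smooth = gaussian_filter1d(dense, sigma=max(2.0, max_len / 100))
    peaks, _ = find_peaks(smooth, prominence=min_prominence_frac * smooth.max())
    peaks = peaks - pad
    peaks = peaks[(peaks >= 0) & (peaks <= max_len)]
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(smooth)) - pad])

    # partition histogram mass by nearest peak
    positions = np.asarray(sorted(dist.hist))
    weights = np.asarray([dist.hist[p] for p in positions], dtype=float)
    nearest = peaks[np.argmin(np.abs(positions[:, None] - peaks[None, :]), axis=1)]
    mass = {int(p): float(weights[nearest == p].sum()) for p in peaks}
    # main: largest mass, larger location wins ties
    main = max(mass, key=lambda p: (mass[p], p))
    total = sum(mass.values())

    minor, minor_frac = None, 0.0
    for p in sorted(mass, key=lambda p: (-mass[p], -p)):
        if p == main:
            continue
        frac = mass[p] / total
        if abs(p - main) >= min_separation_frac * main and frac >= min_minor_mass:
            minor, minor_frac = p, frac
            break
    return ModePair(main_peak=int(main), minor_peak=minor, minor_mass_fraction=minor_frac)


def filter_short_insert_pairs(
    pairs: Sequence[PairAlignment],
    connecting: Iterable[ReadAlignment],
    min_overlap_bp: int = 10,
) -> tuple[list[PairAlignment], list[PairAlignment]]:
    """Partition pairs into (kept, removed) by the connecting-read rule.

    A pair is removed iff some single third-read alignment overlaps both of
    its mate intervals by at least ``min_overlap_bp`` — possible only when
    the true fragment is short enough for one read to bridge the mates.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for aln in connecting:
        if aln.end > aln.start:
            trees[aln.scaffold].addi(aln.start, aln.end, aln.read_id)

    def overlapping_ids(scaffold: str, start: int, end: int) -> set[str]:
        ids = set()
        for iv in trees[scaffold].overlap(start, end):
            if min(iv.end, end) - max(iv.begin, start) >= min_overlap_bp:
                ids.add(iv.data)
        return ids

    kept, removed = [], []
    for p in pairs:
        bridged = False
        if p.same_scaffold and p.scaffold_a in trees:
            ids_a = overlapping_ids(p.scaffold_a, p.pos_a, p.end_a)
            if ids_a:
                bridged = bool(ids_a & overlapping_ids(p.scaffold_b, p.pos_b, p.end_b))
        (removed if bridged else kept).append(p)
    return kept, removed


def dedup_length_spectrum(lengths: Iterable[int], min_count: int) -> DedupSpectrum:
    """Deduplicate a redundant length spectrum.

    Keeps a length with unit weight iff it was observed at least
    ``min_count`` times, then summarizes mean/sd over the deduplicated
    set.  Useful when the same underlying molecule lengths are observed at
    very high redundancy and raw counts would distort the distribution.
    """
    counts = Counter(int(x) for x in lengths)
    if any(length < 0 for length in counts):
        raise ValueError("lengths must be >= 0")
    kept = sorted(length for length, n in counts.items() if n >= min_count)
    if not kept:
        return DedupSpectrum(hist={}, mean=float("nan"), sd=float("nan"))
    arr = np.asarray(kept, dtype=float)
    return DedupSpectrum(hist={length: 1 for length in kept},
                         mean=float(arr.mean()), sd=float(arr.std()))


# --- SAM / TSV ingestion -------------------------------------------------

def read_pairs_from_sam(path: str | Path) -> list[PairAlignment]:
    """Collect primary both-mapped pairs from a SAM/BAM file."""
    pending: dict[str, pysam.AlignedSegment] = {}
    pairs: list[PairAlignment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary or not rec.is_paired:
                continue
            if rec.is_unmapped or rec.mate_is_unmapped:
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            a, b = (mate, rec) if mate.is_read1 else (rec, mate)
            pairs.append(PairAlignment(
                read_id=rec.query_name,
                scaffold_a=a.reference_name, pos_a=a.reference_start,
                end_a=a.reference_end, strand_a="-" if a.is_reverse else "+",
                scaffold_b=b.reference_name, pos_b=b.reference_start,
                end_b=b.reference_end, strand_b="-" if b.is_reverse else "+",
                mapq_a=a.mapping_quality, mapq_b=b.mapping_quality,
            ))
    return pairs


def read_alignments_from_sam(path: str | Path) -> list[ReadAlignment]:
    """Collect primary mapped single-read alignment intervals."""
    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
                continue
            suffix = "/1" if rec.is_read1 else "/2" if rec.is_read2 else ""
            out.append(ReadAlignment(rec.query_name + suffix, rec.reference_name,
                                     rec.reference_start, rec.reference_end))
    return out


_TSV_FIELDS = ("read_id", "scaffold_a", "pos_a", "end_a", "strand_a",
               "scaffold_b", "pos_b", "end_b", "strand_b", "mapq_a", "mapq_b")
_TSV_INT = {"pos_a", "end_a", "pos_b", "end_b", "mapq_a", "mapq_b"}


def read_pairs_from_tsv(path: str | Path) -> list[PairAlignment]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            vals = line.rstrip("\n").split("\t")
            kw = {f: (int(v) if f in _TSV_INT else v)
                  for f, v in zip(_TSV_FIELDS, vals)}
            pairs.append(PairAlignment(**kw))
    return pairs


def write_pairs_tsv(pairs: Iterable[PairAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_TSV_FIELDS) + "\n")
        for p in pairs:
            fh.write("\t".join(str(getattr(p, f)) for f in _TSV_FIELDS) + "\n")
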