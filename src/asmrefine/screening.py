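"""Decontamination, depth-based flagging, erosion filters, read partitioning.

Contaminant homology hits (phiX, cloning vectors, E. coli, organelles,
associated fungi) are consumed as 12-column tabular alignment files and
applied to the assembly either by masking matches with Ns, trimming them
off scaffold ends, or deleting heavily contaminated scaffolds outright.
Read-partitioning helpers extract fully unmapped pairs (input for
complementary assembly) and recruit cleanly mapping pairs against a target
reference panel using a soft-clip budget.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from .errors import CoordinateError

__all__ = [
    "HitInterval",
    "ScreenConfig",
    "RecruitConfig",
    "mask_hits",
    "drop_or_trim_scaffolds",
    "explode_erode_filter",
    "extract_unmapped_pairs",
    "recruit_reads",
    "unique_mapping_filter",
    "read_blast_tab",
    "merge_intervals",
]

ORGANELLE_CLASSES = frozenset({"plastid", "mito"})


@dataclass(frozen=True)
class HitInterval:
    """A contaminant homology hit on the assembly (0-based, half-open)."""

    scaffold: str
    start: int
    end: int
    subject_db: str = "other"
    identity: float = 100.0
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must lie in [0, 100]")


@dataclass
class ScreenConfig:
    erode_bp: int = 50
    min_contig: int = 200
    min_scaffold: int = 500
    drop_fraction: float = 0.5
    depth_flag_threshold: float = 6000.0

    def __post_init__(self) -> None:
        if min(self.erode_bp, self.min_contig, self.min_scaffold) < 0 or \
                self.drop_fraction < 0 or self.depth_flag_threshold < 0:
            raise ValueError("all thresholds must be non-negative")


@dataclass
class RecruitConfig:
    max_softclip_fraction: float = 1.0 / 3.0
    require_both_mates: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_softclip_fraction <= 1.0:
            raise ValueError("max_softclip_fraction must lie in [0, 1]")


def merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and merged."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def mask_hits(assembly: Mapping[str, str], hits: Sequence[HitInterval]) -> dict[str, str]:
    """Replace every hit interval with Ns; sequence lengths are unchanged."""
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        if h.scaffold not in assembly:
            raise CoordinateError(f"hit references unknown scaffold {h.scaffold!r}")
        if h.start < 0 or h.end > len(assembly[h.scaffold]):
            raise CoordinateError(
                f"hit [{h.start},{h.end}) outside scaffold {h.scaffold!r}")
        by_scaffold.setdefault(h.scaffold, []).append((h.start, h.end))

    out = dict(assembly)
    for name, ivs in by_scaffold.items():
        arr = bytearray(out[name], "ascii")
        for s, e in merge_intervals(ivs):
            arr[s:e] = b"N" * (e - s)
        out[name] = arr.decode()
    return out


def drop_or_trim_scaffolds(
    assembly: Mapping[str, str],
    hits: Sequence[HitInterval],
    depth: Mapping[str, float] | None = None,
    cfg: ScreenConfig | None = None,
) -> tuple[dict[str, str], list[str], list[str]]:
    """Delete or clean contaminated scaffolds.

    A scaffold is deleted when the hit-covered fraction reaches
    ``drop_fraction``, or when its mean depth reaches
    ``depth_flag_threshold`` together with an organelle-class hit
    (high-depth scaffolds with plastid/mitochondrial homology are organelle
    sequence, not nuclear).  Otherwise hit regions touching a scaffold end
    are excised and interior hits are masked with Ns.
    """
    cfg = cfg or ScreenConfig()
    depth = depth or {}
    by_scaffold: dict[str, list[HitInterval]] = {}
    for h in hits:
        by_scaffold.setdefault(h.scaffold, []).append(h)

    clean: dict[str, str] = {}
    removed: list[str] = []
    trimmed: list[str] = []
    for name, seq in assembly.items():
        scaffold_hits = by_scaffold.get(name, [])
        if not scaffold_hits:
            clean[name] = seq
            continue
        union = merge_intervals((h.start, h.end) for h in scaffold_hits)
        covered = sum(e - s for s, e in union)
        organelle = any(h.subject_db in ORGANELLE_CLASSES for h in scaffold_hits)
        if covered / len(seq) >= cfg.drop_fraction or \
                (organelle and depth.get(name, 0.0) >= cfg.depth_flag_threshold):
            removed.append(name)
            continue
        lo, hi = 0, len(seq)
        interior: list[tuple[int, int]] = []
        for s, e in union:
            if s <= lo < e or s == lo:
                lo = max(lo, e)
            elif e >= hi:
                hi = min(hi, s)
            else:
                interior.append((s, e))
        arr = bytearray(seq, "ascii")
        for s, e in interior:
            arr[s:e] = b"N" * (e - s)
        clean[name] = arr[lo:hi].decode()
        trimmed.append(name)
    return clean, removed, trimmed


def explode_erode_filter(
    assembly: Mapping[str, str], cfg: ScreenConfig | None = None,
) -> dict[str, str]:
    """Split scaffolds at N-runs, erode contig ends, drop short contigs."""
    cfg = cfg or ScreenConfig()
    out: dict[str, str] = {}
    for name, seq in assembly.items():
        pieces = [p for p in re.split("[Nn]+", seq)]
        idx = 0
        for piece in pieces:
            if not piece:
                continue
            idx += 1
            eroded = piece[cfg.erode_bp: len(piece) - cfg.erode_bp]
            if len(eroded) >= cfg.min_contig:
                out[f"{name}_{idx}"] = eroded
    return out


def extract_unmapped_pairs(
    path: str | Path,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str]]]:
    """Pull read pairs where both mates failed to map, plus singletons.

    Returns ``(pairs, singletons)``: pairs as (name, mate1, mate2)
    sequence tuples; an unmapped mate whose partner mapped goes to
    singletons, as do orphan records.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    pairs: list[tuple[str, str, str]] = []
    singles: list[tuple[str, str]] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary or not rec.is_paired:
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            r1, r2 = (mate, rec) if mate.is_read1 else (rec, mate)
            if r1.is_unmapped and r2.is_unmapped:
                pairs.append((r1.query_name, r1.query_sequence, r2.query_sequence))
            else:
                for r in (r1, r2):
                    if r.is_unmapped:
                        singles.append((r.query_name, r.query_sequence))
    if pending:
        warnings.warn(f"{len(pending)} orphan records routed to singletons")
        for rec in pending.values():
            if rec.is_unmapped:
                singles.append((rec.query_name, rec.query_sequence))
    return pairs, singles


def _clip_fraction(rec: pysam.AlignedSegment) -> float:
    """Clipped fraction over the full read length, hard clips included."""
    clipped = 0
    total = 0
    for op, n in rec.cigartuples or []:
        if op in (4, 5):  # soft, hard
            clipped += n
        if op in (0, 1, 4, 5, 7, 8):  # ops consuming the query (+hard)
            total += n
    return clipped / total if total else 1.0


def recruit_reads(
    path: str | Path, cfg: RecruitConfig | None = None,
) -> list[tuple[str, str, str]]:
    """Recruit read pairs that map cleanly to a target reference panel.

    A mate passes iff it is mapped with a clipped fraction at or below
    ``max_softclip_fraction``; a pair is emitted only when both mates pass
    (``require_both_mates``).
    """
    cfg = cfg or RecruitConfig()
    pending: dict[str, pysam.AlignedSegment] = {}
    out: list[tuple[str, str, str]] = []

    def passes(rec: pysam.AlignedSegment) -> bool:
        return (not rec.is_unmapped) and \
            _clip_fraction(rec) <= cfg.max_softclip_fraction

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary or not rec.is_paired:
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            r1, r2 = (mate, rec) if mate.is_read1 else (rec, mate)
            ok1, ok2 = passes(r1), passes(r2)
            if (ok1 and ok2) or (not cfg.require_both_mates and (ok1 or ok2)):
                out.append((r1.query_name, r1.query_sequence, r2.query_sequence))
    return sorted(out)


def unique_mapping_filter(
    records: Iterable[pysam.AlignedSegment],
    margin: int = 0,
    fallback_mapq: int = 20,
) -> list[pysam.AlignedSegment]:
    """Keep records mapping uniquely: no subdominant match within ``margin``.

    Uses the aligner's best (AS) and second-best (XS) score tags; a record
    passes when XS is absent or ``AS - XS > margin``.  Records without an
    AS tag fall back to a mapping-quality threshold (with a warning).
    """
    kept: list[pysam.AlignedSegment] = []
    warned = False
    for rec in records:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        try:
            best = rec.get_tag("AS")
        except KeyError:
            if not warned:
                warnings.warn("records lack AS score tags; "
                              "falling back to mapping quality")
                warned = True
            if rec.mapping_quality >= fallback_mapq:
                kept.append(rec)
            continue
        try:
            second = rec.get_tag("XS")
        except KeyError:
            kept.append(rec)
            continue
        if best - second > margin:
            kept.append(rec)
    return kept


def read_blast_tab(path: str | Path, subject_db: str = "other",
                   query_is_scaffold: bool = True) -> list[HitInterval]:
    """Read 12-column tabular homology hits (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore).

    1-based inclusive hit coordinates are converted to 0-based half-open.
    By default the query side is taken as the assembly scaffold.
    """
    hits: list[HitInterval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if query_is_scaffold:
                name, lo, hi = f[0], int(f[6]), int(f[7])
            else:
                name, lo, hi = f[1], int(f[8]), int(f[9])
            if lo > hi:
                lo, hi = hi, lo
            hits.append(HitInterval(scaffold=name, start=lo - 1, end=hi,
                                    subject_db=subject_db,
                                    identity=float(f[2]), bitscore=float(f[11])))
    return hits
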