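"""Read-pair consistency checking and misassembly excision.

Every aligned pair votes on the assembly: a pair on one scaffold, in the
expected orientation, with an insert inside the library's mean +/- k*sigma
bounds supports the region it spans (+1 on the consistent vector C); a
pair violating any of those — wrong separation, wrong orientation, or mates
on different scaffolds — casts a negative vote (+1 on the inconsistent
vector I) over the region where its missing mate should have been.
Regions where the net score C - I is negative are excised, splitting the
scaffold into consistent blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import ReferenceMismatchError
from .insert_stats import InsertDistribution, PairAlignment, _orientation_ok

__all__ = [
    "ConsistencyConfig",
    "SupportProfile",
    "BreakResult",
    "score_support",
    "break_assembly",
    "write_bed",
]


@dataclass
class ConsistencyConfig:
    """Parameters of the consistency check.

    sigma_mult: insert bounds are mean +/- sigma_mult * sd (3 by default).
    min_region: minimum net-negative run length (bp) that triggers excision;
        shorter flickers are ignored.
    end_slack: distance (bp) from a scaffold end within which cross-scaffold
        evidence is ignored (pairs legitimately bridging into a neighbouring
        scaffold); defaults to the upper insert bound.
    min_block: retained blocks shorter than this are dropped (counted as
        excised).
    """

    sigma_mult: float = 3.0
    min_region: int = 50
    end_slack: int | None = None
    min_block: int = 200

    def __post_init__(self) -> None:
        if self.sigma_mult <= 0 or self.min_region < 1:
            raise ValueError("sigma_mult must be > 0 and min_region >= 1")


@dataclass
class SupportProfile:
    """Per-base consistent (C) and inconsistent (I) evidence vectors."""

    consistent: dict[str, np.ndarray] = field(default_factory=dict)
    inconsistent: dict[str, np.ndarray] = field(default_factory=dict)

    def net(self, scaffold: str) -> np.ndarray:
        return self.consistent[scaffold].astype(np.int64) - self.inconsistent[scaffold]

    def add(self, other: "SupportProfile") -> "SupportProfile":
        """Sum evidence from another library's profile (in place)."""
        for name, vec in other.consistent.items():
            self.consistent[name] = self.consistent.get(name, 0) + vec
        for name, vec in other.inconsistent.items():
            self.inconsistent[name] = self.inconsistent.get(name, 0) + vec
        return self


@dataclass
class BreakResult:
    blocks: list[tuple[str, int, int]]
    breakpoints: list[tuple[str, int, int]]
    n_blocks_before: int
    n_blocks_after: int


def _scaffold_lengths(assembly: Mapping[str, str] | Mapping[str, int]) -> dict[str, int]:
    return {name: (v if isinstance(v, int) else len(v)) for name, v in assembly.items()}


def score_support(
    assembly: Mapping[str, str] | Mapping[str, int],
    pairs: Iterable[PairAlignment],
    dist: InsertDistribution,
    cfg: ConsistencyConfig | None = None,
) -> SupportProfile:
    """Accumulate per-base consistent/inconsistent evidence over an assembly.

    ``assembly`` maps scaffold name to sequence (or to length).  Each
    consistent pair adds +1 on C over its span; each mate of an
    inconsistent pair adds +1 on I over the interval extending mean +
    sigma_mult*sd from its alignment toward where its mate should lie.
    Cross-scaffold mates within ``end_slack`` of the relevant scaffold end
    contribute nothing.
    """
    cfg = cfg or ConsistencyConfig()
    lengths = _scaffold_lengths(assembly)
    lo, hi = dist.bounds(cfg.sigma_mult)
    ext = int(round(dist.mean + cfg.sigma_mult * dist.sd))
    end_slack = cfg.end_slack if cfg.end_slack is not None else int(round(hi))

    # difference arrays; cumsum at the end gives the per-base vectors
    c_diff = {name: np.zeros(n + 1, dtype=np.int32) for name, n in lengths.items()}
    i_diff = {name: np.zeros(n + 1, dtype=np.int32) for name, n in lengths.items()}

    def penalize(scaffold: str, pos: int, end: int, strand: str, cross: bool) -> None:
        n = lengths[scaffold]
        if strand == "+":
            if cross and n - pos <= end_slack:
                return
            a, b = pos, min(pos + ext, n)
        else:
            if cross and end <= end_slack:
                return
            a, b = max(end - ext, 0), end
        if b > a:
            i_diff[scaffold][a] += 1
            i_diff[scaffold][b] -= 1

    for p in pairs:
        for name in (p.scaffold_a, p.scaffold_b):
            if name not in lengths:
                raise ReferenceMismatchError(f"scaffold {name!r} not in assembly")
        if p.same_scaffold and _orientation_ok(p, dist.expected_orientation) \
                and lo <= p.insert_size <= hi:
            a, b = min(p.pos_a, p.pos_b), max(p.end_a, p.end_b)
            c_diff[p.scaffold_a][a] += 1
            c_diff[p.scaffold_a][min(b, lengths[p.scaffold_a])] -= 1
        else:
            cross = not p.same_scaffold
            penalize(p.scaffold_a, p.pos_a, p.end_a, p.strand_a, cross)
            penalize(p.scaffold_b, p.pos_b, p.end_b, p.strand_b, cross)

    prof = SupportProfile()
    for name, n in lengths.items():
        prof.consistent[name] = np.cumsum(c_diff[name][:n])
        prof.inconsistent[name] = np.cumsum(i_diff[name][:n])
    return prof


def _negative_runs(net: np.ndarray, min_region: int) -> list[tuple[int, int]]:
    neg = net < 0
    if not neg.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], neg.view(np.int8), [0]))))
    runs = edges.reshape(-1, 2)
    return [(int(s), int(e)) for s, e in runs if e - s >= min_region]


def break_assembly(
    assembly: Mapping[str, str],
    prof: SupportProfile,
    cfg: ConsistencyConfig | None = None,
) -> tuple[dict[str, str], BreakResult]:
    """Excise net-negative regions and split scaffolds into blocks.

    Maximal runs of net score < 0 spanning at least ``min_region`` bp are
    removed; the flanking retained blocks become separate sequences named
    ``<scaffold>_partN``.  Retained blocks shorter than ``min_block`` are
    dropped (reported among the excised intervals), so excised and retained
    intervals always partition the original coordinates.
    """
    cfg = cfg or ConsistencyConfig()
    out: dict[str, str] = {}
    blocks: list[tuple[str, int, int]] = []
    excised: list[tuple[str, int, int]] = []

    for name, seq in assembly.items():
        n = len(seq)
        runs = _negative_runs(prof.net(name), cfg.min_region) if name in prof.consistent else []
        if not runs:
            candidates = [(0, n)]
        else:
            candidates = []
            prev = 0
            for s, e in runs:
                if s > prev:
                    candidates.append((prev, s))
                excised.append((name, s, e))
                prev = e
            if prev < n:
                candidates.append((prev, n))

        kept = []
        for s, e in candidates:
            if e - s >= cfg.min_block:
                kept.append((s, e))
            else:
                excised.append((name, s, e))
        if len(kept) == 1 and kept[0] == (0, n):
            out[name] = seq
            blocks.append((name, 0, n))
        else:
            for i, (s, e) in enumerate(kept, 1):
                out[f"{name}_part{i}"] = seq[s:e]
                blocks.append((name, s, e))

    return out, BreakResult(
        blocks=blocks,
        breakpoints=sorted(excised),
        n_blocks_before=len(assembly),
        n_blocks_after=len(out),
    )


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, s, e in intervals:
            fh.write(f"{name}\t{s}\t{e}\n")
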