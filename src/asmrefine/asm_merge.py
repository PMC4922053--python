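"""Overlap-layout-consensus merging of partially redundant assemblies.

Contigs from multiple input assemblies are merged through an overlap
graph: candidate contig pairs are found by shared minimizers, verified by
banded edit-distance alignment (dovetail or containment geometry only),
contained contigs are absorbed, transitive edges reduced, and simple paths
concatenated.  At branch points a path is followed only when scaffolding
links carried over from the input assemblies support exactly one branch —
otherwise the repeat stays collapsed as a single copy.  Separate entry
points perform tip absorption (spurious dead ends) and self-collapse of
uncollapsed haplotypes.

Orientation bookkeeping uses oriented nodes ``(contig, orient)`` with
orient 0 = forward, 1 = reverse complement; every dovetail overlap yields
a directed edge between oriented nodes plus its complement edge.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InputError
from .seqio import revcomp

__all__ = [
    "Overlap",
    "MergeConfig",
    "Link",
    "find_overlaps",
    "merge_round",
    "tip_merge",
    "collapse_haplotypes",
    "merge_pipeline",
    "read_links_tsv",
    "write_overlaps_tsv",
]


@dataclass
class Overlap:
    """A dovetail or containment alignment between two contigs.

    Coordinates are 0-based half-open on the forward strand of each
    contig; for ``strand == "opposite"`` the aligned B interval is the
    reverse complement of ``b[b_start:b_end]``.
    """

    contig_a: str
    contig_b: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    strand: str  # "same" | "opposite"
    length: int
    edit_distance: int

    @property
    def divergence(self) -> float:
        return self.edit_distance / self.length if self.length else 0.0


@dataclass
class MergeConfig:
    """Thresholds for the merge pipeline.

    rounds: successive (min_overlap bp, max_divergence) passes; the
        defaults run a strict round (2,400 bp, 1.5 %) followed by a
        permissive one (4,000 bp, 10 %) that merges allelic regions.
    tip_min_overlap: smallest overlap allowing a dead-end contig to be
        absorbed.
    minimizer_k/minimizer_w: seeding parameters for candidate pairing.
    """

    rounds: list[tuple[int, float]] = field(
        default_factory=lambda: [(2400, 0.015), (4000, 0.10)])
    tip_min_overlap: int = 250
    minimizer_k: int = 15
    minimizer_w: int = 10
    min_minimizer_hits: int = 3
    max_bucket: int = 200

    def __post_init__(self) -> None:
        for mo, md in self.rounds:
            if mo < self.tip_min_overlap or not 0.0 <= md <= 1.0:
                raise ValueError("require min_overlap >= tip_min_overlap and "
                                 "max_divergence in [0, 1]")


@dataclass(frozen=True)
class Link:
    """An input-assembly scaffolding adjacency: a (orient_a) then b (orient_b)."""

    contig_a: str
    orient_a: int  # 0 forward, 1 reverse
    contig_b: str
    orient_b: int
    gap: int = 100


# --- minimizer seeding ---------------------------------------------------

_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _v in zip(b"ACGT", range(4)):
    _LUT[_b] = _v


def _minimizers(seq: str, k: int, w: int) -> list[tuple[int, int, int]]:
    """(position, canonical code, strand) minimizers of a sequence."""
    raw = _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if len(raw) < k + w:
        return []
    bad = raw == 255
    windows = sliding_window_view(np.where(bad, 0, raw).astype(np.int64), k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = windows @ powers
    rev = (3 - windows[:, ::-1]) @ powers
    canon = np.minimum(fwd, rev)
    strand = (fwd <= rev).astype(np.int8)  # 1: forward is canonical
    invalid = sliding_window_view(bad, k).any(axis=1)
    canon = np.where(invalid, np.iinfo(np.int64).max, canon)

    win = sliding_window_view(canon, w)
    pos = win.argmin(axis=1) + np.arange(len(win))
    pos = np.unique(pos)
    pos = pos[~invalid[pos]]
    return [(int(p), int(canon[p]), int(strand[p])) for p in pos]


def _candidate_pairs(
    contigs: Mapping[str, str], cfg: MergeConfig, include_self: bool = False,
) -> dict[tuple[str, str, str], list[int]]:
    """Map (contig_a, contig_b, strand) -> list of implied diagonals."""
    names = list(contigs)
    index: dict[int, list[tuple[int, int, int]]] = defaultdict(list)
    mins: dict[int, list[tuple[int, int, int]]] = {}
    for ci, name in enumerate(names):
        mm = _minimizers(contigs[name], cfg.minimizer_k, cfg.minimizer_w)
        mins[ci] = mm
        for p, v, s in mm:
            index[v].append((ci, p, s))

    diags: dict[tuple[str, str, str], list[int]] = defaultdict(list)
    k = cfg.minimizer_k
    for entries in index.values():
        if len(entries) < 2 or len(entries) > cfg.max_bucket:
            continue
        for i in range(len(entries)):
            ci, pa, sa = entries[i]
            for j in range(i + 1, len(entries)):
                cj, pb, sb = entries[j]
                if ci == cj and not include_self:
                    continue
                if ci > cj:
                    (ci2, pa2, sa2), (cj2, pb2, sb2) = entries[j], entries[i]
                else:
                    (ci2, pa2, sa2), (cj2, pb2, sb2) = entries[i], entries[j]
                na, nb = names[ci2], names[cj2]
                if sa2 == sb2:
                    diags[(na, nb, "same")].append(pa2 - pb2)
                else:
                    len_b = len(contigs[nb])
                    diags[(na, nb, "opposite")].append(pa2 - (len_b - k - pb2))
    return diags


def find_overlaps(
    contigs: Mapping[str, str],
    min_overlap: int = 2400,
    max_divergence: float = 0.015,
    cfg: MergeConfig | None = None,
) -> list[Overlap]:
    """Find all qualifying dovetail/containment overlaps between contigs.

    Candidate pairs come from shared minimizers; each candidate's implied
    diagonal (median of minimizer offsets) defines an end-anchored overlap
    region that is verified with banded edit-distance alignment.  Reverse
    complement overlaps are reported with ``strand="opposite"``.
    """
    if not isinstance(contigs, Mapping):
        items = list(contigs)
        if len({n for n, _ in items}) != len(items):
            raise InputError("duplicate contig names")
        contigs = dict(items)
    cfg = cfg or MergeConfig()
    overlaps: list[Overlap] = []
    seen: set[tuple[str, str]] = set()
    for (na, nb, strand), dlist in sorted(_candidate_pairs(contigs, cfg).items()):
        if len(dlist) < cfg.min_minimizer_hits:
            continue
        a, b = contigs[na], contigs[nb]
        bf = b if strand == "same" else revcomp(b)
        d = int(np.median(dlist))
        sa, ea = max(0, d), min(len(a), d + len(bf))
        olen = ea - sa
        if olen < min_overlap:
            continue
        sb, eb = sa - d, ea - d
        band = int(max_divergence * olen) + 16
        res = edlib.align(a[sa:ea], bf[sb:eb], mode="NW", task="distance", k=band)
        dist = res["editDistance"]
        if dist < 0 or dist / olen > max_divergence:
            continue
        if (na, nb) in seen:
            continue  # keep the first (better-supported) orientation
        seen.add((na, nb))
        if strand == "opposite":
            sb, eb = len(b) - eb, len(b) - sb
        overlaps.append(Overlap(contig_a=na, contig_b=nb, a_start=sa, a_end=ea,
                                b_start=sb, b_end=eb, strand=strand,
                                length=olen, edit_distance=dist))
    return overlaps


# --- oriented-graph machinery -------------------------------------------

Node = tuple[str, int]


def _rev(u: Node) -> Node:
    return (u[0], 1 - u[1])


def _oseq(contigs: Mapping[str, str], u: Node) -> str:
    s = contigs[u[0]]
    return s if u[1] == 0 else revcomp(s)


def _is_containment(ovl: Overlap, contigs: Mapping[str, str]) -> str | None:
    """Return the name of the contained contig, or None for a dovetail."""
    if ovl.b_start == 0 and ovl.b_end == len(contigs[ovl.contig_b]):
        return ovl.contig_b
    if ovl.a_start == 0 and ovl.a_end == len(contigs[ovl.contig_a]):
        return ovl.contig_a
    return None


def _directed_edges(
    overlaps: Iterable[Overlap], contigs: Mapping[str, str],
) -> dict[Node, list[tuple[Node, int]]]:
    """Directed oriented edges (suffix of u matches prefix of v) with overlap length."""
    edges: dict[Node, list[tuple[Node, int]]] = defaultdict(list)

    def add(u: Node, v: Node, olen: int) -> None:
        edges[u].append((v, olen))
        edges[_rev(v)].append((_rev(u), olen))

    for o in overlaps:
        if o.contig_a not in contigs or o.contig_b not in contigs:
            continue
        if _is_containment(o, contigs) is not None:
            continue
        la, lb = len(contigs[o.contig_a]), len(contigs[o.contig_b])
        A, B = o.contig_a, o.contig_b
        if o.strand == "same":
            if o.a_end == la and o.b_start == 0:
                add((A, 0), (B, 0), o.length)
            elif o.b_end == lb and o.a_start == 0:
                add((B, 0), (A, 0), o.length)
        else:
            if o.a_end == la and o.b_end == lb:
                add((A, 0), (B, 1), o.length)
            elif o.a_start == 0 and o.b_start == 0:
                add((B, 1), (A, 0), o.length)
    # deduplicate parallel edges, keep the longest overlap
    for u in edges:
        best: dict[Node, int] = {}
        for v, olen in edges[u]:
            best[v] = max(best.get(v, 0), olen)
        edges[u] = sorted(best.items(), key=lambda t: (-t[1], t[0]))
    return edges


def _transitive_reduce(edges: dict[Node, list[tuple[Node, int]]]) -> None:
    """Remove edges u->w when u->v->w exists with a longer u->v overlap."""
    out_sets = {u: {v for v, _ in lst} for u, lst in edges.items()}
    drop: set[tuple[Node, Node]] = set()
    for u, lst in edges.items():
        for i, (v, l1) in enumerate(lst):
            for w, l2 in lst[i + 1:]:  # sorted by olen desc: l2 <= l1
                if w in out_sets.get(v, ()):
                    drop.add((u, w))
                    drop.add((_rev(w), _rev(u)))
    if drop:
        for u in edges:
            edges[u] = [(v, l) for v, l in edges[u] if (u, v) not in drop]


def _remove_contained(
    contigs: dict[str, str], overlaps: Sequence[Overlap],
) -> tuple[dict[str, str], list[Overlap]]:
    dropped: set[str] = set()
    for o in sorted(overlaps, key=lambda o: -o.length):
        if o.contig_a in dropped or o.contig_b in dropped:
            continue
        la, lb = len(contigs[o.contig_a]), len(contigs[o.contig_b])
        name = _is_containment(o, contigs)
        if name is None:
            continue
        if o.b_end - o.b_start == lb and o.a_end - o.a_start == la:
            # mutual containment (near-identical contigs): keep the longer,
            # break length ties toward the lexicographically smaller name
            if (la, o.contig_b) < (lb, o.contig_a):
                dropped.add(o.contig_a)
            else:
                dropped.add(o.contig_b)
        else:
            dropped.add(name)
    kept = {n: s for n, s in contigs.items() if n not in dropped}
    live = [o for o in overlaps
            if o.contig_a not in dropped and o.contig_b not in dropped]
    return kept, live


def _link_supports(
    u: Node, v: Node,
    links: Sequence[Link],
    constituents: Mapping[str, list[tuple[str, int]]],
) -> bool:
    """Does some input-scaffold link assert u (then) v in these orientations?"""
    members_u = {(n, o ^ u[1]) for n, o in constituents.get(u[0], [(u[0], 0)])}
    members_v = {(n, o ^ v[1]) for n, o in constituents.get(v[0], [(v[0], 0)])}
    for lk in links:
        if (lk.contig_a, lk.orient_a) in members_u and \
                (lk.contig_b, lk.orient_b) in members_v:
            return True
        if (lk.contig_b, lk.orient_b ^ 1) in members_u and \
                (lk.contig_a, lk.orient_a ^ 1) in members_v:
            return True
    return False


def _assemble_chains(
    contigs: Mapping[str, str],
    succ: Mapping[Node, tuple[Node, int, int]],
    constituents: Mapping[str, list[tuple[str, int]]] | None = None,
) -> tuple[dict[str, str], dict[str, list[tuple[str, int]]]]:
    """Concatenate contigs along mutually agreed successor edges.

    ``succ[u] = (v, overlap_len, gap_len)``; overlap regions keep the
    longer constituent's sequence, gaps are filled with Ns.
    """
    constituents = constituents or {}
    pred: dict[Node, Node] = {}
    for u, (v, _, _) in succ.items():
        pred[v] = u

    out: dict[str, str] = {}
    out_members: dict[str, list[tuple[str, int]]] = {}
    visited: set[str] = set()
    for name in contigs:
        if name in visited:
            continue
        u: Node = (name, 0)
        guard = 0
        while u in pred and pred[u][0] != name and guard <= len(contigs):
            u = pred[u]
            guard += 1
        chain: list[tuple[Node, int, int]] = [(u, 0, 0)]  # (node, olen_in, gap_in)
        visited.add(u[0])
        while u in succ:
            v, olen, gap = succ[u]
            if v[0] in visited:
                break
            chain.append((v, olen, gap))
            visited.add(v[0])
            u = v

        members: list[tuple[str, int]] = []
        seq = ""
        prev_len = 0
        for node, olen, gap in chain:
            piece = _oseq(contigs, node)
            for n, o in constituents.get(node[0], [(node[0], 0)]):
                members.append((n, o ^ node[1]))
            if not seq:
                seq = piece
            elif gap > 0:
                seq = seq + "N" * gap + piece
            elif prev_len >= len(piece):
                seq = seq + piece[olen:]
            else:
                seq = seq[: len(seq) - olen] + piece
            prev_len = len(piece)
        if len(chain) == 1:
            out[name if name == chain[0][0][0] else chain[0][0][0]] = \
                contigs[chain[0][0][0]]
            out_members[chain[0][0][0]] = members
        else:
            new_name = "+".join(n for (n, _), _, _ in chain)
            out[new_name] = seq
            out_members[new_name] = members
    return out, out_members


def merge_round(
    contigs: Mapping[str, str],
    overlaps: Sequence[Overlap],
    links: Sequence[Link] | None = None,
    constituents: Mapping[str, list[tuple[str, int]]] | None = None,
) -> tuple[dict[str, str], dict[str, list[tuple[str, int]]]]:
    """One merging pass: containment removal, transitive reduction, unitigs.

    At a branch node a path continues only if the links support exactly one
    outgoing branch; otherwise the node ends its unitig and the repeat is
    left as a single collapsed copy.
    """
    links = links or []
    constituents = dict(constituents or {})
    contigs, live = _remove_contained(dict(contigs), overlaps)
    edges = _directed_edges(live, contigs)
    _transitive_reduce(edges)

    def resolve(u: Node) -> tuple[Node, int] | None:
        outs = edges.get(u, [])
        if len(outs) == 1:
            return outs[0]
        if len(outs) > 1 and links:
            supported = [e for e in outs
                         if _link_supports(u, e[0], links, constituents)]
            if len(supported) == 1:
                return supported[0]
        return None

    succ: dict[Node, tuple[Node, int, int]] = {}
    for u in list(edges):
        r = resolve(u)
        if r is None:
            continue
        v, olen = r
        back = resolve(_rev(v))
        if back is not None and back[0] == _rev(u):
            succ[u] = (v, olen, 0)
    # keep one orientation per physical junction (drop complement edges)
    cleaned: dict[Node, tuple[Node, int, int]] = {}
    used: set[frozenset] = set()
    for u, (v, olen, gap) in succ.items():
        key = frozenset({(u, v), (_rev(v), _rev(u))})
        if key in used:
            continue
        used.add(key)
        cleaned[u] = (v, olen, gap)
    return _assemble_chains(contigs, cleaned, constituents)


def tip_merge(
    contigs: Mapping[str, str],
    overlaps: Sequence[Overlap],
    tip_min_overlap: int = 250,
) -> dict[str, str]:
    """Absorb dead-end contigs into longer neighbours.

    A tip (contig with at most one overlap neighbour) whose overlap with a
    longer contig reaches ``tip_min_overlap`` is absorbed: dropped when
    contained, or merged into the neighbour (extending it with the tip's
    overhang) when dovetailing.  Interior nodes are never modified.
    """
    contigs = dict(contigs)
    neigh: dict[str, set[str]] = defaultdict(set)
    for o in overlaps:
        neigh[o.contig_a].add(o.contig_b)
        neigh[o.contig_b].add(o.contig_a)
    tips = {n for n in contigs if len(neigh[n]) <= 1}

    edges = _directed_edges(overlaps, contigs)
    for o in sorted(overlaps, key=lambda o: -o.length):
        if o.length < tip_min_overlap:
            continue
        a, b = o.contig_a, o.contig_b
        if a not in contigs or b not in contigs:
            continue
        tip, partner = (a, b) if a in tips and len(contigs[a]) < len(contigs[b]) \
            else (b, a) if b in tips and len(contigs[b]) < len(contigs[a]) else (None, None)
        if tip is None:
            continue
        if _is_containment(o, contigs) == tip:
            del contigs[tip]
            continue
        # dovetail: extend the partner with the tip overhang
        for u, outs in list(edges.items()):
            for v, olen in outs:
                if olen != o.length:
                    continue
                if u[0] == partner and v[0] == tip:
                    merged = _oseq(contigs, u) + _oseq(contigs, v)[olen:]
                    contigs[partner] = merged if u[1] == 0 else revcomp(merged)
                    del contigs[tip]
                    break
                if u[0] == tip and v[0] == partner:
                    merged = _oseq(contigs, u)[: len(contigs[tip]) - olen] + _oseq(contigs, v)
                    contigs[partner] = merged if v[1] == 0 else revcomp(merged)
                    del contigs[tip]
                    break
            if tip not in contigs:
                break
    return contigs


def collapse_haplotypes(
    assembly: Mapping[str, str],
    min_overlap: int = 4000,
    max_divergence: float = 0.03,
    cfg: MergeConfig | None = None,
) -> dict[str, str]:
    """Merge self-overlaps so each locus keeps one haplotype copy.

    Near-identical contigs (uncollapsed haplotypes, duplicated assembly
    artifacts) meeting the overlap thresholds are merged keeping the
    longer contig's sequence; the total assembly length never increases.
    """
    cfg = cfg or MergeConfig()
    contigs = dict(assembly)
    overlaps = find_overlaps(contigs, min_overlap, max_divergence, cfg)
    contigs, live = _remove_contained(contigs, overlaps)
    edges = _directed_edges(live, contigs)

    # greedy chain building: longest overlaps first, each contig end used once
    parent: dict[str, str] = {n: n for n in contigs}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def port(u: Node, side: str) -> tuple[str, str]:
        # physical port of an oriented node: right of (n,0) is (n,'R'), etc.
        if side == "R":
            return (u[0], "R" if u[1] == 0 else "L")
        return (u[0], "L" if u[1] == 0 else "R")

    used_ports: set[tuple[str, str]] = set()
    flat = sorted(
        ((u, v, olen) for u, outs in edges.items() for v, olen in outs),
        key=lambda t: (-t[2], t[0], t[1]))
    succ: dict[Node, tuple[Node, int, int]] = {}
    accepted: set[frozenset] = set()
    for u, v, olen in flat:
        key = frozenset({(u, v), (_rev(v), _rev(u))})
        if key in accepted:
            continue
        pu, pv = port(u, "R"), port(v, "L")
        if pu in used_ports or pv in used_ports:
            continue
        if find(u[0]) == find(v[0]):
            continue
        used_ports.update((pu, pv))
        parent[find(u[0])] = find(v[0])
        accepted.add(key)
        succ[u] = (v, olen, 0)
    merged, _ = _assemble_chains(contigs, succ)
    return merged


def merge_pipeline(
    assemblies: Sequence[Mapping[str, str]],
    links: Sequence[Link] | None = None,
    cfg: MergeConfig | None = None,
) -> dict[str, str]:
    """Full merge: per-round overlap merging, tip absorption, link reinsertion.

    Coherent links (both endpoints survive in different output sequences
    with preserved relative orientation) are reinserted as scaffold joins
    with N-gaps of the link's gap estimate.
    """
    cfg = cfg or MergeConfig()
    links = links or []
    contigs: dict[str, str] = {}
    for i, asm in enumerate(assemblies):
        for name, seq in asm.items():
            key = name if name not in contigs else f"a{i}|{name}"
            contigs[key] = seq
    constituents: dict[str, list[tuple[str, int]]] = {n: [(n, 0)] for n in contigs}

    for min_ov, max_div in cfg.rounds:
        # iterate to a fixed point: merging chains creates new containments
        # and resolves branches, enabling further merges
        for _ in range(10):
            before = (len(contigs), sum(len(s) for s in contigs.values()))
            overlaps = find_overlaps(contigs, min_ov, max_div, cfg)
            contigs, constituents = merge_round(contigs, overlaps, links, constituents)
            if (len(contigs), sum(len(s) for s in contigs.values())) == before:
                break

    last_round = cfg.rounds[-1]
    overlaps = find_overlaps(contigs, cfg.tip_min_overlap, last_round[1], cfg)
    surviving = set(contigs)
    contigs = tip_merge(contigs, overlaps, cfg.tip_min_overlap)
    constituents = {n: m for n, m in constituents.items() if n in contigs}
    for n in contigs:
        constituents.setdefault(n, [(n, 0)])

    if links:
        contigs = _reinsert_links(contigs, constituents, links)
    return contigs


def _reinsert_links(
    contigs: dict[str, str],
    constituents: Mapping[str, list[tuple[str, int]]],
    links: Sequence[Link],
) -> dict[str, str]:
    where: dict[str, tuple[str, int]] = {}
    for out_name, members in constituents.items():
        for n, o in members:
            where[n] = (out_name, o)

    edges: list[tuple[Node, Node, int]] = []
    for lk in links:
        if lk.contig_a not in where or lk.contig_b not in where:
            continue
        (oa, ca), (ob, cb) = where[lk.contig_a], where[lk.contig_b]
        if oa == ob:
            continue  # already merged; the link is satisfied internally
        flip_a = ca ^ lk.orient_a
        flip_b = cb ^ lk.orient_b
        edges.append(((oa, flip_a), (ob, flip_b), max(int(lk.gap), 1)))

    parent = {n: n for n in contigs}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    used_ports: set[tuple[str, str]] = set()
    succ: dict[Node, tuple[Node, int, int]] = {}
    for u, v, gap in edges:
        pu = (u[0], "R" if u[1] == 0 else "L")
        pv = (v[0], "L" if v[1] == 0 else "R")
        if pu in used_ports or pv in used_ports or find(u[0]) == find(v[0]):
            continue
        used_ports.update((pu, pv))
        parent[find(u[0])] = find(v[0])
        succ[u] = (v, 0, gap)
    merged, _ = _assemble_chains(contigs, succ)
    return merged


# --- text I/O ------------------------------------------------------------

def read_links_tsv(path: str | Path) -> list[Link]:
    """Read links as `contig_a orient_a contig_b orient_b gap` (orient +/-)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            a, ori_a, b, ori_b, gap = line.split()[:5]
            out.append(Link(a, 0 if ori_a == "+" else 1,
                            b, 0 if ori_b == "+" else 1, int(gap)))
    return out


def write_overlaps_tsv(overlaps: Iterable[Overlap], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#contig_a\tcontig_b\ta_start\ta_end\tb_start\tb_end\t"
                 "strand\tlength\tedit_distance\tdivergence\n")
        for o in overlaps:
            fh.write(f"{o.contig_a}\t{o.contig_b}\t{o.a_start}\t{o.a_end}\t"
                     f"{o.b_start}\t{o.b_end}\t{o.strand}\t{o.length}\t"
                     f"{o.edit_distance}\t{o.divergence:.4f}\n")
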