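"""Gene-duplication diagnostics and small annotation filters.

Given homology searches of a proteome against itself and against a related
species, these diagnostics ask whether apparent gene duplications are real
or are assembly artifacts (uncollapsed haplotypes): reciprocal best-hit
paralog pairs, genes whose closest paralog outscores their best ortholog,
the fraction of paralog pairs sharing an ortholog, and a comparison of
heterozygous-SNV counts between duplicated and single-copy genes (real
duplicates accumulate variants independently, so their het-SNV counts stay
high; uncollapsed haplotypes split the reads and deplete them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

__all__ = [
    "read_hit_table",
    "best_hits",
    "reciprocal_best_hits",
    "closer_paralog_genes",
    "shared_best_hit_fraction",
    "snv_class_comparison",
    "SnvSummary",
    "lncrna_filter",
    "transcripts_per_gene",
    "truncate2",
    "nearest_rank_quantile",
]


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Load 12-column tabular homology hits into a (query, subject,
    identity, bitscore) frame, dropping self-hits."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 11], names=["query", "subject", "identity", "bitscore"])
    return df[df["query"] != df["subject"]].reset_index(drop=True)


def best_hits(table: pd.DataFrame) -> tuple[dict[str, str], set[str]]:
    """Unique top-bitscore subject per query; tied queries go to a tie set."""
    best: dict[str, str] = {}
    ties: set[str] = set()
    for query, grp in table.groupby("query"):
        top = grp["bitscore"].max()
        winners = sorted(set(grp.loc[grp["bitscore"] == top, "subject"]))
        if len(winners) == 1:
            best[query] = winners[0]
        else:
            ties.add(query)
    return best, ties


def reciprocal_best_hits(
    a_vs_b: pd.DataFrame, b_vs_a: pd.DataFrame,
) -> tuple[list[tuple[str, str]], set[str]]:
    """Reciprocal best-hit pairs; bitscore ties form no pair.

    Returns the sorted pair list and the set of tied queries (emitted for
    auditability).  Passing the same within-species table twice yields
    paralogous RBH pairs, deduplicated as unordered pairs.
    """
    fwd, ties_f = best_hits(a_vs_b)
    rev, ties_r = best_hits(b_vs_a)
    pairs: set[tuple[str, str]] = set()
    for x, y in fwd.items():
        if rev.get(y) == x:
            pairs.add(tuple(sorted((x, y))))
    return sorted(pairs), ties_f | ties_r


def closer_paralog_genes(
    self_hits: pd.DataFrame, ortho_hits: pd.DataFrame,
    metric: str = "bitscore",
) -> tuple[set[str], set[str]]:
    """Genes whose best within-species paralog outscores their best ortholog.

    Returns ``(closer, eligible)``: the qualifying gene set and the
    denominator (genes with a cross-species hit at all).  Inclusion uses a
    strict inequality on ``metric`` (bitscore by default).
    """
    best_self = self_hits.groupby("query")[metric].max()
    best_ortho = ortho_hits.groupby("query")[metric].max()
    eligible = set(best_ortho.index)
    closer = {
        g for g in eligible
        if g in best_self.index and best_self[g] > best_ortho[g]
    }
    return closer, eligible


def shared_best_hit_fraction(
    rbh_pairs: Sequence[tuple[str, str]],
    ortho_hits: pd.DataFrame,
) -> tuple[int, float]:
    """Count pairs whose members share an identical cross-species best hit.

    Returns ``(count, percentage)`` with the percentage over all pairs,
    rounded to one decimal.
    """
    if not rbh_pairs:
        raise InsufficientDataError("no pairs: percentage undefined")
    best, _ = best_hits(ortho_hits)
    count = sum(1 for x, y in rbh_pairs
                if x in best and y in best and best[x] == best[y])
    return count, round(100.0 * count / len(rbh_pairs), 1)


def nearest_rank_quantile(values: Sequence[float], q: float) -> float:
    """Nearest-rank quantile: value at rank ceil(q*n) of the sorted sample."""
    if not values:
        raise InsufficientDataError("empty sample")
    ordered = sorted(values)
    rank = max(1, math.ceil(q * len(ordered)))
    return ordered[rank - 1]


@dataclass
class SnvSummary:
    mean_dup: float
    mean_singleton: float
    q70_dup: float
    q70_singleton: float
    t_statistic: float
    df: float
    p_value: float


def snv_class_comparison(
    snv_counts: Mapping[str, float],
    duplicates: Iterable[str],
    singletons: Iterable[str],
) -> SnvSummary:
    """Compare heterozygous-SNV counts between duplicated and singleton genes.

    Reports per-class mean and 70 % nearest-rank quantile, and Welch's
    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2) with Welch-Satterthwaite
    degrees of freedom (class 1 = duplicates).
    """
    dup_set, sing_set = set(duplicates), set(singletons)
    if dup_set & sing_set:
        raise ValueError("duplicate and singleton gene sets must be disjoint")
    xs = [snv_counts[g] for g in sorted(dup_set) if g in snv_counts]
    ys = [snv_counts[g] for g in sorted(sing_set) if g in snv_counts]
    if len(xs) < 2 or len(ys) < 2:
        raise InsufficientDataError("each class needs at least 2 genes")
    n1, n2 = len(xs), len(ys)
    m1 = sum(xs) / n1
    m2 = sum(ys) / n2
    v1 = sum((x - m1) ** 2 for x in xs) / (n1 - 1)
    v2 = sum((y - m2) ** 2 for y in ys) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2) if se2 > 0 else 0.0
    if se2 > 0 and v1 > 0 or v2 > 0:
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)) \
            if se2 > 0 else float(n1 + n2 - 2)
    else:
        df = float(n1 + n2 - 2)
    p = 2.0 * stats.t.sf(abs(t), df) if se2 > 0 else 1.0
    return SnvSummary(
        mean_dup=m1, mean_singleton=m2,
        q70_dup=nearest_rank_quantile(xs, 0.7),
        q70_singleton=nearest_rank_quantile(ys, 0.7),
        t_statistic=t, df=df, p_value=p,
    )


def lncrna_filter(
    transcripts: Iterable[tuple[str, int, float]],
    min_length: int = 200,
    max_small_ncrna_cover: float = 0.8,
) -> list[str]:
    """Keep long non-coding candidates: length strictly above ``min_length``
    and small-ncRNA-covered fraction strictly below the cutoff."""
    kept = []
    for tid, length, covered in transcripts:
        if not 0.0 <= covered <= 1.0:
            raise ValueError(f"covered fraction out of [0,1] for {tid!r}")
        if length > min_length and covered < max_small_ncrna_cover:
            kept.append(tid)
    return kept


def transcripts_per_gene(n_transcripts: int, n_genes: int) -> float:
    """Transcript-to-gene ratio (full precision; truncate for display)."""
    if n_genes <= 0:
        raise ZeroDivisionError("gene count must be positive")
    return n_transcripts / n_genes


def truncate2(x: float) -> float:
    """Two-decimal truncation used when printing ratios."""
    return math.floor(x * 100) / 100
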