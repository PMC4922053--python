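"""Consensus polishing: apply homozygous alternative variants to an assembly.

Variant calling against its own read data exposes positions where the
assembly disagrees with the consensus of the reads; substituting the
homozygous alternative alleles (hom-ref and heterozygous calls are left
alone) yields a polished sequence.  Variants are applied left-to-right
with offset tracking; overlapping calls resolve leftmost-wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

__all__ = [
    "VariantRecord",
    "select_polishing_variants",
    "apply_variants",
    "filter_by_length",
]

_VALID = set("ACGTN")


@dataclass(frozen=True)
class VariantRecord:
    """A genotyped variant (0-based position, explicit ref/alt strings)."""

    scaffold: str
    pos: int
    ref: str
    alt: str
    genotype_class: str = "hom-alt"  # hom-ref | het | hom-alt
    filter_status: str = "PASS"

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if set(self.ref.upper()) - _VALID or set(self.alt.upper()) - _VALID:
            raise ValueError("alleles must be over ACGTN")


def _classify(gt: tuple) -> tuple[str, int | None]:
    """Map a GT tuple to a genotype class and the selected alt index."""
    alleles = [a for a in gt if a is not None]
    if len(alleles) < len(gt) or not alleles:
        return "het", None  # half-calls treated conservatively as het
    if all(a == 0 for a in alleles):
        return "hom-ref", None
    if len(set(alleles)) == 1:
        return "hom-alt", alleles[0]
    return "het", None


def select_polishing_variants(
    vcf: str | Path | Iterable[VariantRecord],
) -> list[VariantRecord]:
    """Select PASS (or unfiltered) homozygous-alternative records.

    Accepts a VCF path (plain or bgzipped) or pre-parsed records.
    Multiallelic records keep only the genotype-selected allele.
    Malformed records are skipped with a warning count.
    """
    if not isinstance(vcf, (str, Path)):
        return [v for v in vcf if v.genotype_class == "hom-alt"
                and v.filter_status in ("PASS", ".", "")]

    out: list[VariantRecord] = []
    skipped = 0
    with pysam.VariantFile(str(vcf)) as fh:
        for rec in fh:
            try:
                filters = list(rec.filter.keys())
                if filters and filters != ["PASS"]:
                    continue
                if not rec.samples:
                    skipped += 1
                    continue
                gt = rec.samples[0].get("GT")
                if gt is None:
                    skipped += 1
                    continue
                cls, alt_idx = _classify(tuple(gt))
                if cls != "hom-alt":
                    continue
                alt = rec.alleles[alt_idx]
                if alt is None or rec.ref is None:
                    skipped += 1
                    continue
                out.append(VariantRecord(
                    scaffold=rec.chrom, pos=rec.start, ref=rec.ref.upper(),
                    alt=alt.upper(), genotype_class="hom-alt",
                    filter_status="PASS"))
            except (ValueError, KeyError, IndexError):
                skipped += 1
    if skipped:
        warnings.warn(f"skipped {skipped} malformed or incomplete VCF records")
    return out


def apply_variants(
    assembly: Mapping[str, str],
    variants: Sequence[VariantRecord],
) -> tuple[dict[str, str], list[tuple[VariantRecord, str]]]:
    """Apply substitutions and indels, returning the consensus and a report.

    Variants are applied per scaffold, left-to-right, with cumulative
    offset tracking.  When variants overlap, the leftmost is applied and
    later conflicting ones are skipped; records whose ref allele does not
    match the assembly are rejected.  Untouched positions are identical to
    the input.  Report statuses: applied | skipped-overlap | rejected-ref |
    rejected-scaffold.
    """
    by_scaffold: dict[str, list[VariantRecord]] = {}
    report: list[tuple[VariantRecord, str]] = []
    for v in variants:
        if v.scaffold not in assembly:
            report.append((v, "rejected-scaffold"))
            continue
        by_scaffold.setdefault(v.scaffold, []).append(v)

    out = dict(assembly)
    for name, vs in by_scaffold.items():
        seq = assembly[name]
        pieces: list[str] = []
        cursor = 0
        for v in sorted(vs, key=lambda v: (v.pos, v.pos + len(v.ref))):
            if v.pos < cursor:
                report.append((v, "skipped-overlap"))
                continue
            if seq[v.pos:v.pos + len(v.ref)].upper() != v.ref.upper():
                report.append((v, "rejected-ref"))
                continue
            pieces.append(seq[cursor:v.pos])
            pieces.append(v.alt)
            cursor = v.pos + len(v.ref)
            report.append((v, "applied"))
        pieces.append(seq[cursor:])
        out[name] = "".join(pieces)
    return out, report


def filter_by_length(assembly: Mapping[str, str], min_len: int = 500) -> dict[str, str]:
    """Keep sequences at least ``min_len`` bp long."""
    return {n: s for n, s in assembly.items() if len(s) >= min_len}
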