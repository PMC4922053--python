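"""Thin FASTA/FASTQ helpers shared across modules.

Sequences are handled as plain upper-case strings keyed by record name.
Coordinates everywhere in the package are 0-based, half-open.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path: str | Path) -> str:
    name = Path(path).name.removesuffix(".gz")
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an ordered name -> sequence dict."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    records = (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items())
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)

def iter_reads(path: str | Path) -> Iterator[str]:
    """Yield raw sequences from a FASTA or FASTQ file (optionally gzipped)."""
    fmt = _sniff_format(path)
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield str(rec.seq).upper()


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (name, sequence) pairs as FASTQ with uniform dummy qualities."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
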