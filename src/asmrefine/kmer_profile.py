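"""K-mer spectrum profiling: counting, peak detection, genome-size estimation.

A k-mer spectrum is the histogram of how many distinct k-mer species occur
at each multiplicity (sequencing depth) in a read set.  For a diploid
sample it typically shows a homozygous peak at the sequencing depth d and a
heterozygous peak near d/2 (k-mers present on only one haplotype), with an
error tail at low multiplicity.  Genome size follows from dividing the
total k-mer count by the main-peak depth; the heterozygous fraction is
approximated with a constrained two-component Gaussian mixture over the
species counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import uniform_filter1d
from scipy.optimize import curve_fit

from .errors import EmptySpectrumError, NoSignalError
from .seqio import iter_reads

__all__ = [
    "KmerSpectrum",
    "PeakSet",
    "GenomeSizeEstimate",
    "count_kmers",
    "detect_peaks",
    "estimate_genome_size",
    "estimate_het_ratio",
    "cvalue_to_bp",
    "BP_PER_PICOGRAM",
]

#: 1 pg of DNA corresponds to 978 Mbp.
BP_PER_PICOGRAM = 978_000_000


@dataclass
class KmerSpectrum:
    """Histogram of distinct k-mer species per multiplicity."""

    k: int
    hist: dict[int, int]

    def __post_init__(self) -> None:
        if any(m < 1 for m in self.hist):
            raise ValueError("multiplicities must be >= 1")
        if any(c < 0 for c in self.hist.values()):
            raise ValueError("species counts must be >= 0")

    @property
    def total_kmers(self) -> int:
        """Total number of counted k-mer instances, sum(multiplicity * count)."""
        return sum(m * c for m, c in self.hist.items())

    @property
    def max_multiplicity(self) -> int:
        return max(self.hist) if self.hist else 0

    def dense(self) -> np.ndarray:
        """Counts as an array indexed by multiplicity (index 0 unused)."""
        arr = np.zeros(self.max_multiplicity + 1, dtype=float)
        for m, c in self.hist.items():
            arr[m] = c
        return arr

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for m in sorted(self.hist):
                fh.write(f"{m}\t{self.hist[m]}\n")

    @classmethod
    def read(cls, path: str | Path, k: int = 0) -> "KmerSpectrum":
        hist: dict[int, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                m, c = line.split()[:2]
                hist[int(m)] = hist.get(int(m), 0) + int(c)
        return cls(k=k, hist=hist)


@dataclass
class PeakSet:
    """Peaks called on a (smoothed) k-mer spectrum."""

    error_cutoff: int
    hom_depth: int
    het_depth: int | None = None
    peak_heights: dict[int, float] = field(default_factory=dict)


@dataclass
class GenomeSizeEstimate:
    size_bp: float
    method: str
    het_ratio: float | None = None
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.size_bp <= 0:
            raise ValueError("size_bp must be > 0")
        if self.het_ratio is not None and not 0.0 <= self.het_ratio <= 1.0:
            raise ValueError("het_ratio must lie in [0, 1]")


# 2-bit base codes; 255 marks non-ACGT.
_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _v in zip(b"ACGT", range(4)):
    _BASE_LUT[_b] = _v
    _BASE_LUT[_b + 32] = _v  # lower case


def _canonical_codes(seq_block: str, k: int) -> np.ndarray:
    """Canonical integer codes of all valid k-mers in a concatenated block."""
    raw = np.frombuffer(seq_block.encode(), dtype=np.uint8)
    codes = _BASE_LUT[raw]
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    bad = codes == 255
    windows = sliding_window_view(np.where(bad, 0, codes).astype(np.int64), k)
    valid = ~sliding_window_view(bad, k).any(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = windows[valid] @ powers
    rev = (3 - windows[valid][:, ::-1]) @ powers
    return np.minimum(fwd, rev)


def count_kmers(reads: Iterable[str] | str | Path, k: int) -> KmerSpectrum:
    """Count canonical k-mers in a read set and build the spectrum.

    Parameters
    ----------
    reads:
        An iterable of sequence strings, or a path to a FASTA/FASTQ file
        (optionally gzipped).
    k:
        Odd k-mer length in [3, 31].  Canonical counting takes the
        lexicographic minimum of each k-mer and its reverse complement;
        k-mers containing non-ACGT characters are skipped.
    """
    if not (3 <= k <= 31) or k % 2 == 0:
        raise ValueError("k must be odd and within [3, 31]")
    if isinstance(reads, (str, Path)):
        reads = iter_reads(reads)

    chunks: list[np.ndarray] = []
    buf: list[str] = []
    buf_len = 0
    for seq in reads:
        buf.append(seq)
        buf_len += len(seq) + 1
        if buf_len >= 4_000_000:
            chunks.append(_canonical_codes("N".join(buf), k))
            buf, buf_len = [], 0
    if buf:
        chunks.append(_canonical_codes("N".join(buf), k))
    if not chunks:
        raise EmptySpectrumError("no reads supplied")

    codes = np.concatenate(chunks)
    if codes.size == 0:
        raise EmptySpectrumError(f"no k-mers of length {k} in input")
    _, per_species = np.unique(codes, return_counts=True)
    mults, n_species = np.unique(per_species, return_counts=True)
    hist = {int(m): int(c) for m, c in zip(mults, n_species)}
    return KmerSpectrum(k=k, hist=hist)


def _smooth(dense: np.ndarray) -> np.ndarray:
    # centered moving average, window 3; edge handled by repetition so
    # well-separated symmetric peaks are not shifted
    out = dense.copy()
    out[1:] = uniform_filter1d(dense[1:], size=3, mode="nearest")
    return out


def detect_peaks(spec: KmerSpectrum, min_depth: int = 3) -> PeakSet:
    """Locate the error cutoff and the homozygous/heterozygous peaks.

    The error cutoff is the first local minimum of the smoothed histogram
    above multiplicity 1 (falling back to ``min_depth``); the homozygous
    depth is the global mode above the cutoff; a heterozygous peak is
    reported only if a local maximum exists within [0.35, 0.65] times the
    homozygous depth.
    """
    if not spec.hist:
        raise NoSignalError("empty spectrum")
    s = _smooth(spec.dense())
    n = len(s) - 1  # max multiplicity

    cutoff = min_depth
    for d in range(2, n):
        if s[d] <= s[d - 1] and s[d] < s[d + 1]:
            cutoff = d
            break

    region = np.arange(cutoff + 1, n + 1)
    if region.size == 0:
        raise NoSignalError("no multiplicities above the error cutoff")
    hom = int(region[np.argmax(s[region])])
    left = s[hom - 1] if hom - 1 >= 1 else -np.inf
    right = s[hom + 1] if hom + 1 <= n else -np.inf
    is_local_max = s[hom] >= max(left, right) and (s[hom] > left or s[hom] > right)
    if not is_local_max or s[hom] <= 0:
        raise NoSignalError("no peak above the error cutoff")

    het: int | None = None
    lo = max(cutoff + 1, int(math.ceil(0.35 * hom)))
    hi = int(math.floor(0.65 * hom))
    best_height = -np.inf
    for d in range(max(lo, 2), min(hi, n - 1) + 1):
        if s[d] >= s[d - 1] and s[d] >= s[d + 1] and (s[d] > s[d - 1] or s[d] > s[d + 1]):
            if s[d] > best_height:
                best_height = s[d]
                het = d

    heights = {hom: float(spec.hist.get(hom, 0))}
    if het is not None:
        heights[het] = float(spec.hist.get(het, 0))
    return PeakSet(error_cutoff=cutoff, hom_depth=hom, het_depth=het, peak_heights=heights)


def estimate_genome_size(spec: KmerSpectrum, peaks: PeakSet) -> GenomeSizeEstimate:
    """Genome size as total k-mer instances divided by the main-peak depth."""
    if peaks.hom_depth <= 0:
        raise ZeroDivisionError("homozygous peak depth must be > 0")
    return GenomeSizeEstimate(size_bp=spec.total_kmers / peaks.hom_depth, method="total/peak")


def _two_gauss(d: np.ndarray, a1: float, s1: float, a2: float, s2: float,
               m1: float, m2: float) -> np.ndarray:
    g1 = a1 * np.exp(-0.5 * ((d - m1) / s1) ** 2)
    g2 = a2 * np.exp(-0.5 * ((d - m2) / s2) ** 2)
    return g1 + g2


def estimate_het_ratio(spec: KmerSpectrum, peaks: PeakSet) -> GenomeSizeEstimate:
    """Heterozygosity proxy from a constrained two-component mixture.

    Component means are pinned at the detected heterozygous and homozygous
    depths; only amplitudes and widths are fitted.  ``het_ratio`` is the
    heterozygous component's share of the non-error species mass.  The
    returned size estimate counts heterozygous-component k-mer instances at
    half weight, since each heterozygous site contributes two species at
    half depth.
    """
    if peaks.het_depth is None:
        size = estimate_genome_size(spec, peaks)
        return GenomeSizeEstimate(size_bp=size.size_bp, method="mixture",
                                  het_ratio=0.0, warning="no heterozygous peak detected")

    dense = spec.dense()
    hom, het = peaks.hom_depth, peaks.het_depth
    d_max = min(len(dense) - 1, int(round(1.75 * hom)))
    d = np.arange(peaks.error_cutoff + 1, d_max + 1, dtype=float)
    y = dense[peaks.error_cutoff + 1 : d_max + 1]

    p0 = (max(dense[het], 1.0), max(het * 0.2, 1.0),
          max(dense[hom], 1.0), max(hom * 0.2, 1.0))
    try:
        popt, _ = curve_fit(
            lambda dd, a1, s1, a2, s2: _two_gauss(dd, a1, s1, a2, s2, het, hom),
            d, y, p0=p0,
            bounds=([0, 0.3, 0, 0.3], [np.inf, hom, np.inf, hom]),
            maxfev=20_000,
        )
    except RuntimeError:
        size = estimate_genome_size(spec, peaks)
        return GenomeSizeEstimate(size_bp=size.size_bp, method="mixture",
                                  het_ratio=0.0, warning="mixture fit failed")
    a1, s1, a2, s2 = popt
    mass_het = a1 * s1 * math.sqrt(2 * math.pi)
    mass_hom = a2 * s2 * math.sqrt(2 * math.pi)
    het_ratio = float(mass_het / (mass_het + mass_hom)) if mass_het + mass_hom > 0 else 0.0

    # corrected size: per-depth attribution of instances to the het component
    all_d = np.arange(peaks.error_cutoff + 1, len(dense), dtype=float)
    counts = dense[peaks.error_cutoff + 1 :]
    comp_het = a1 * np.exp(-0.5 * ((all_d - het) / s1) ** 2)
    comp_hom = a2 * np.exp(-0.5 * ((all_d - hom) / s2) ** 2)
    denom = comp_het + comp_hom
    f_het = np.where(denom > 0, comp_het / np.maximum(denom, 1e-300), 0.0)
    corrected_total = float(np.sum(all_d * counts * (1.0 - 0.5 * f_het)))
    return GenomeSizeEstimate(size_bp=corrected_total / hom, method="mixture",
                              het_ratio=min(max(het_ratio, 0.0), 1.0))


def cvalue_to_bp(cvalue_pg: float) -> float:
    """Convert a C-value in picograms to base pairs (1 pg = 978 Mbp)."""
    if cvalue_pg <= 0:
        raise ValueError("C-value must be positive")
    return cvalue_pg * BP_PER_PICOGRAM
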