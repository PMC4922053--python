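# asmrefine

A toolkit for refining draft genome assemblies of heterozygous organisms,
built around the workflow used for large plant genomes assembled from
fosmid pools: profile the genome from k-mer spectra, model library insert
sizes, break scaffolds where read pairs contradict the sequence, merge
partially redundant assemblies through an overlap graph, collapse
uncollapsed haplotypes, screen out contaminants, and polish the consensus
with homozygous variants. A first-class simulator generates every input
class — diploid genomes, clone pools, paired-end/mate-pair reads with
bimodal insert contamination, and misjoined assemblies with truth
breakpoints — so the whole pipeline is testable end to end without any
external data.

## Who it is for

Assembly engineers and genome-project bioinformaticians who already have
reads, alignments (SAM/BAM), homology hits (BLAST outfmt 6) and variant
calls (VCF) from standard tools, and need the *refinement* arithmetic in
between: the toolkit consumes those standard formats and never re-runs a
mapper or assembler.

## The models in brief

- **K-mer spectrum profiling.** For reads at sequencing depth *d*, the
  spectrum of distinct k-mer species per multiplicity shows a homozygous
  peak near *d* and, in heterozygous samples, a second peak near *d*/2.
  Genome size is `G = total_kmers / hom_peak_depth`; the heterozygous
  fraction is approximated by a two-component Gaussian mixture with means
  pinned at the two peaks. C-values convert at 1 pg = 978 Mbp.
- **Pair-consistency checking.** Each aligned pair votes: +1 on a
  consistent vector C over its span when it maps to one scaffold, in the
  expected orientation, with insert inside `mean ± 3σ`; otherwise +1 on an
  inconsistent vector I over the interval where the missing mate should
  lie. Regions with `C − I < 0` are excised, splitting scaffolds into
  consistent blocks.
- **Overlap merging.** Contig pairs seeded by shared minimizers are
  verified with banded edit distance (dovetail/containment geometry only);
  contained contigs are absorbed, transitive edges reduced, and unitigs
  concatenated — at branch points only when input-assembly scaffolding
  links support exactly one continuation, so unsupported repeats stay
  collapsed. Default rounds: 2,400 bp at ≤1.5 % divergence, then 4,000 bp
  at ≤10 % to merge allelic regions; tips merge down to 250 bp;
  haplotype self-collapse uses 4 kb at ≤3 %.
- **Clone-pool statistics.** Pools of *n* clones of length *L* on a genome
  of size *G* follow Lander–Waterman coverage `1 − exp(−nL/G)`; the
  simulator's interval sweep reports covered, overlapped and redundant
  base fractions and the fraction of overlaps mixing haplotypes.

## Worked example

```python
from asmrefine.kmer_profile import (KmerSpectrum, PeakSet,
                                    estimate_genome_size, cvalue_to_bp)
from asmrefine.pool_sim import lw_covered_fraction

total = 71_902_584_399              # 17-mer instances in a read subset
q, r = divmod(total, 52)
spec = KmerSpectrum(k=17, hist={52: q, 1: r})
est = estimate_genome_size(spec, PeakSet(error_cutoff=3, hom_depth=52))
print(f"genome size: {est.size_bp/1e9:.2f} Gb")      # genome size: 1.38 Gb
print(f"median C-value: {cvalue_to_bp(1.59)/1e9:.2f} Gb")  # 1.56 Gb
cov = lw_covered_fraction(1600, 36_700, 1.38e9)
print(f"pool coverage: {100*cov:.1f} %")             # pool coverage: 4.2 %
```

A spectrum totalling ~71.9 billion 17-mers with its main peak at 52x
implies a 1.38 Gb genome; flow-cytometry C-values put the same genome at
1.42–2.28 Gb (median 1.56 Gb); and a pool of 1,600 fosmid clones of
36.7 kb covers about 4.2 % of such a genome, which is what makes pooled
assemblies locally haploid.

The command-line front end exposes the same operations
(`asmrefine --help`): `kspec`, `inserts`, `check`, `merge`, `screen`,
`polish`, `simulate`, `dupdiag`, `annot`. Every run writes a JSON report
with its parameters and summary metrics.

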