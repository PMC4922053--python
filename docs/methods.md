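# Methods

This note documents the models, parameter choices and numerical decisions
behind each asmrefine module, what the synthetic-data generator does and
does not emulate, and the known limitations.

## K-mer spectrum profiling (`kmer_profile`)

K-mers are counted canonically (lexicographic minimum of a k-mer and its
reverse complement), the default for spectrum tools; k must be odd so a
k-mer never equals its own reverse complement. Counting is in-memory
(vectorised 2-bit encoding, one 64-bit code per window); the module
targets desk-scale inputs, not streaming counters.

Peak calling smooths the histogram with a centred moving average of
window 3 — wide enough to stabilise modes on sparse histograms, narrow
enough not to shift well-separated peaks. The error cutoff is the first
local minimum of the smoothed histogram above multiplicity 1, falling
back to a floor of 3; the homozygous depth is the global mode above the
cutoff and must be a strict local maximum (a flat histogram therefore
raises a no-signal error rather than returning its arbitrary argmax).
A heterozygous peak is reported only if a local maximum exists in
[0.35, 0.65] × hom_depth, the window where a diploid's half-depth peak
must fall.

Genome size is `total_kmers / hom_depth` at full precision; rounding is
presentation. The heterozygosity proxy fits two Gaussians in species
space with means pinned at the called peaks (amplitudes and widths free,
fitted by least squares over multiplicities from the error cutoff to
1.75 × hom_depth so the repeat tail does not inflate the homozygous
component). `het_ratio` is the heterozygous component's share of the
non-error species mass. The corrected genome size counts heterozygous
k-mer instances at half weight, since each heterozygous site produces two
species at half depth. This is an explicit approximation to full
mixture-likelihood estimators of spectrum structure; it is accurate to
roughly a factor of two against exact haplotype k-mer enumeration on
simulated diploids, which is the fidelity the toolkit claims for it.

## Insert-size modelling (`insert_stats`)

The insert of a pair is the outer span `max(end) − min(pos)` on one
scaffold. Usable pairs must be in the library's expected orientation —
FR for paired-end, RF for mate-pair, configurable because junction-based
mate-pair protocols differ — with both mates at mapping quality ≥ 20.
Mean and SD are computed after trimming 1 % from each tail: empirical
insert distributions carry mismapping outliers, and the trimmed moments
are what the ±3σ consistency bounds should reflect. With fewer than 100
usable pairs the estimate is refused.

Mode detection smooths the dense histogram with a Gaussian kernel
(σ = max(2, span/100)) after zero-padding both ends so plateaus touching
the histogram boundary still register as peaks. Histogram mass is
partitioned by nearest peak; the main mode carries the larger mass (ties
break toward the larger location, so a contaminant short mode is never
promoted over an equal-mass true mode); a minor mode must be separated by
≥ 25 % of the main location and carry ≥ 5 % of the mass — smaller bumps
are sampling noise.

Short-insert pairs are removed when a single third read overlaps both
mate intervals by ≥ 10 bp (configurable): only a genuinely short fragment
can be bridged by one read, so this is geometric evidence independent of
the insert histogram. The filter is a strict partition of its input.

Fosmid-end length spectra sequenced at extreme redundancy are
deduplicated by keeping each length once iff it was observed at least
`min_count` times (default use: 100); mean/SD are then computed on the
deduplicated set. This flattens peak amplitude but preserves location.

## Consistency checking (`consistency`)

Votes are ±1 per pair; the module deliberately uses unweighted counts so
the net score is a simple majority of the evidence. Inconsistent
evidence is localised by extending from each offending mate by
`mean + sigma_mult·sd` in the direction its mate should lie — the paper
trail for a bad join is where the missing mate belongs. This
localisation rule is this package's own choice; only the ±3σ bound and
the sum-of-vectors excision rule are externally specified. Cross-scaffold
mates within `end_slack` (default: the upper insert bound) of the
relevant scaffold end contribute nothing, since such pairs legitimately
bridge into neighbouring sequences.

Excision removes maximal net-negative runs of ≥ `min_region` bp (default
50, suppressing single-base flicker); flanking blocks become
`<scaffold>_partN`; retained blocks under 200 bp are reclassified as
excised so retained ∪ excised always partitions the original
coordinates. Profiles from multiple libraries sum elementwise before
breaking.

## Assembly merging (`asm_merge`)

Candidate contig pairs share ≥ 3 minimizers (k = 15, w = 10, canonical);
the median of matched-minimizer offsets fixes a diagonal, which defines
an end-anchored overlap verified by banded edit distance (edlib, band =
max_divergence × length + 16). Only dovetail and containment geometries
arise by construction. Divergence is edit distance over the overlap
length. Repeat-heavy minimizer buckets above 200 entries are skipped as
seeds (overlaps are still found through their other minimizers).

Merging per round: contained contigs are absorbed (near-identical pairs
keep the longer, ties the lexicographically smaller name, for
determinism); transitive edges (u→w shadowed by u→v→w with a longer u→v
overlap) are removed; unitigs follow mutually-unique successor edges.
At a branch, a continuation is taken only when the carried scaffolding
links support exactly one outgoing edge — both the contig content and the
link orientations are checked against the merged contig's constituents —
otherwise the walk stops and the repeat remains a single collapsed copy.
Across an overlap the longer contig's sequence is kept; no base-level
consensus is attempted at this stage (polishing is a separate module).
Each round iterates overlap discovery + merging to a fixed point (capped
at 10 passes): chains formed in one pass create new containments and
resolve branches for the next, which replaces the external
scaffolding/gap-filling steps a production pipeline would interleave.
Defaults are two rounds — 2,400 bp / 1.5 % (strict), then 4,000 bp / 10 %
(allelic) — followed by tip absorption down to 250 bp and reinsertion of
still-coherent links (both endpoints surviving in different output
sequences, orientations preserved) as N-gap scaffold joins.

Haplotype self-collapse runs overlap discovery on the assembly against
itself at 4 kb / 3 % — the 3 % ceiling translates a mapper-style
error+mismatch budget into a single divergence bound — drops
containments, and chains remaining dovetails greedily (longest overlap
first, each contig end used once, cycles refused), which guarantees the
total length never increases.

## Screening (`screening`)

Homology hits arrive as 12-column tabular files; the toolkit never runs
the search itself. Masking replaces the union of hit intervals with Ns,
preserving length. Scaffold removal uses two rules: hit-covered fraction
≥ 0.5 (the published pipeline reports outcomes, not its threshold; 0.5 is
this package's default and is configurable), or mean depth ≥ 6000x
together with an organelle-class hit — organelles are present at
copy numbers far above nuclear depth. Otherwise terminal hits are
trimmed off and interior hits masked. The explode/erode filter splits at
N-runs, erodes 50 bp per contig end (assembler ends are error-prone) and
drops contigs under 200 bp; final scaffold filtering keeps ≥ 500 bp.

Read partitioning: "unmapped pairs" means both mates unmapped (primary
records only); a mate whose partner mapped is preserved separately as a
singleton for transparency. Recruitment against a reference panel passes
a mate iff it is mapped with (soft + hard clipped)/full read length ≤ 1/3
— hard clips count because they also represent unaligned read sequence —
and emits a pair only when both mates pass. Unique-mapping filtering
keeps records whose best alignment score (AS) beats the second best (XS)
by more than a margin (default 0, so ties drop); records without score
tags fall back to a mapping-quality threshold with a warning.

## Polishing (`polish`)

Only PASS (or unfiltered) homozygous-alternative genotypes are applied;
heterozygous calls and half-calls are conservatively ignored — polishing
must not pick alleles. Multiallelic records keep the genotype-selected
allele. Application is left-to-right with offset tracking; overlapping
variants resolve leftmost-wins and the loser is reported, as are
ref-mismatch rejections (non-fatal). Output length equals input length
plus the net indel delta of applied records.

## Synthetic data (`pool_sim`)

The generator emulates the study conditions the rest of the toolkit is
tested under: a diploid genome as substitution-only haplotypes (indel
heterozygosity is deliberately excluded so truth coordinates align
trivially between haplotypes), optional repeat content as duplicated
segments; clone pools with uniform starts and truncated-normal lengths,
defaulting to N(36.7 kb, 4.97 kb) — the empirical fosmid insert
distribution — with uniform haplotype choice; read libraries as FR or RF
pairs with Gaussian insert mixtures (the 725/300 bp bimodal
contamination pattern is reproducible via `minor_*`), uniform
substitution errors, and optional chimeric pairs; and misjoins as
cut-and-swap events between scaffolds with exact junction coordinates
and a coordinate lift for truth alignments (mates straddling a block
boundary are dropped, as a mapper would clip them).

Pool statistics use an interval sweep, never per-base arrays, so
full-scale genomes (1.38 Gb) run in milliseconds; the sweep is verified
against per-base depth arrays on multi-megabase cases. In the sparse
regime the redundant-base fraction converges to the Lander–Waterman form
`1 − (1 − e^(−c))/c` with c = nL/G, and the overlapped-base fraction to
`1 − e^(−c)`; for diploid pools about half of overlapped positions mix
haplotypes, with the excess above one half coming from depth ≥ 3 stacks.

What the simulations do not capture: real base-quality error profiles,
PCR duplicates, cloning bias, indel polymorphism, and mapper-specific
alignment artefacts. Passing tests demonstrate the refinement arithmetic
is correct under controlled conditions, not that any particular mapper's
output will satisfy the same assumptions.

## Problem sizes used in the test suite

The simulation-backed checks run at: 50 pools of 1,600 clones on a
1.38 Gb genome (overlap statistics); a 1 Mb, 10-scaffold assembly with 20
misjoins at 30x spanning-pair coverage (misjoin recovery, with a clean
control); 96 three-clone pool assemblies tiling 500 kb (merge
reconstruction); and oracle equivalences at 20 × 2 kb contigs (overlap
detection vs exhaustive per-diagonal enumeration), 5 Mb (pool sweep vs
per-base arrays), 30 genes (reciprocal best hits vs double-loop
enumeration) and 500 variants (polish round trip). These sizes were
chosen as the smallest at which the statistics of interest are
well-resolved.

## Duplication diagnostics (`annot_analysis`)

Similarity comparisons use bitscore (identity available as an
alternative); best hits must be unique — bitscore ties form no pair and
are emitted in a tie list for audit. Quantiles are nearest-rank. Welch's
t is computed from its definition, `t = (m₁−m₂)/√(s₁²/n₁ + s₂²/n₂)` with
Welch–Satterthwaite degrees of freedom; the scientific logic is that
genuine recent duplicates accumulate heterozygous SNVs independently at
both loci while uncollapsed haplotypes split read support and deplete
them, so the sign of t discriminates the two explanations. Genome-wide
published counts depend on external proteomes and are exercised only as
printed-ratio arithmetic.

## Known limitations

- Overlap detection assumes minimizer-dense, moderately divergent
  (≲10 %) overlaps; highly repetitive contigs whose every minimizer
  bucket overflows can evade seeding.
- The mixture-based heterozygosity is a factor-of-two proxy, not a
  population-genetic estimate.
- Link reinsertion does not re-estimate gap sizes from alignments; it
  trusts the input link's gap estimate.
- The consistency check requires spanning-pair coverage; junctions near
  scaffold ends (within the insert length) are indistinguishable from
  ordinary end effects.
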