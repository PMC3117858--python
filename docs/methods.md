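# Methods

`rrlchip` re-implements, as a tested library, the classic pipeline for
building a medium-density SNP genotyping array from pooled
reduced-representation sequencing: library design by restriction digest and
size selection, read QC, pooled pileup SNP calling with allele-frequency
estimation by read counting, priority- and spacing-driven panel selection,
array-performance classification, and two-point linkage placement of
markers that have no position on the reference assembly. This note
describes the models, the defaults and the design choices; nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Reduced-representation library model

A complete digest places a cut at every exact occurrence of the enzyme's
recognition site (default AluI, `AG^CT`, a blunt four-cutter); fragments
are the intervals between consecutive cuts and tile each chromosome
exactly. AluI's site is its own reverse complement, so scanning the
forward strand finds every cut; for non-palindromic enzymes both strands
are scanned. The size window is inclusive on both ends, matching how gel
excision ranges are quoted (e.g. 125–200 bp). Fold depth is defined as
sequenced bases landing on the selection divided by selected bases; note
that with 36 bp reads anchored at fragment ends, the *realized* depth on
covered bases is higher than this figure (a 160 bp fragment exposes only
~72 bp to reads), and the internal fragment middle is uncovered. On a
uniform-composition genome a four-cutter cuts every 256 bp on average, and
the 125–200 bp window captures roughly 10% of a random genome — larger
than the few percent seen on a real genome, whose fragment-length
distribution is broader.

## Synthetic data

The generators exist to give every pipeline stage a ground truth:

* **Genome** — chromosomes in five size classes (macro, intermediate,
  micro, unplaced contig, mitochondrion) with i.i.d. bases at a per-class
  GC content (defaults 0.42 macro → 0.52 micro, mirroring the GC
  enrichment of small, gene-dense avian chromosomes). No repeats, so
  almost every 36-mer is unique; real genomes map less cleanly.
* **Truth SNPs** — biallelic, Poisson-placed at a configurable density
  (the worked examples and reproduction script use 1/300 bp, a typical
  divergence between commercial chicken lines and the reference), with
  the minor allele frequency drawn uniformly from a flat high-MAF window
  (default 0.15–0.5, mean 0.325) and assigned to the major/minor side at
  random. Frequencies are drawn independently per population unless a
  sharing probability is set.
* **Pooled reads** — each 36 bp read pair picks a size-selected fragment
  (probability proportional to length) and a template haplotype i.i.d.
  from the pool's 2N founder haplotypes (N = 25 diploids by default, no
  DNA-quantity imbalance); haplotype alleles at truth SNPs are fixed once
  per pool as Bernoulli draws from the population frequency. Read 1 is
  the fragment's first 36 bases and read 2 the first 36 bases of its
  reverse complement, so both start with `CT` on internal AluI fragments.
  Errors are uniform substitutions; qualities follow a two-state model
  (high-Q body with an occasional all-low-Q read) so the mean-quality
  filter has positive cases. No indels, adapters, or position-dependent
  error profiles.
* **Families** — full-sib families with founders drawn in Hardy–Weinberg
  proportions from per-marker allele frequencies. Gametes recombine
  without interference (Haldane) at the rate implied by the cM gap;
  Kosambi is used only for reporting distances, because the recombination
  fraction is what downstream estimation sees. `min_het_parents > 0`
  redraws founder alleles per marker until at least that many parents are
  heterozygous — the standard linkage scenario uses 3 of 4, emulating a
  mapping panel restricted to markers that actually segregate in the
  families (a marker with no heterozygous parent yields no informative
  meioses and is unmappable by any method).

Because the synthetic genome is repeat-free and errors are uniform,
passing tests demonstrate the pipeline's logic and calibration, not its
robustness to repeat-rich genomes, indels, or structured error profiles.

## Read QC

Four filters with per-filter accounting (first-failing attribution, in
the fixed order quality → motif → homopolymer): mean Phred below 12
drops a read; a read not starting with `CT` drops (applied to both mates
by default, since both ends of a blunt AluI fragment start at a cut; a
flag restricts it to first mates); a single-base run longer than 17 (for
36 bp reads, ≥ half the read) drops. After alignment, all reads stacking
at a start site — the (chromosome, start, strand) key, the natural unit
for RRL data where reads pile at cut sites — observed more than 5× the
estimated average depth are removed. Average depth is estimated as
aligned bases over reference bases covered at least once. N bases never
match the motif and break homopolymer runs. Dropping one mate never drops
the other.

## Mapping and SNP calling

The internal mapper is a seed-and-extend unique mapper adequate for
synthetic 36-mers: exact non-overlapping seeds of length
`read_len // (max_mismatch + 1)` (pigeonhole guarantees a clean seed),
verification allowing at most two mismatches (the conventional short-read
setting for 36-mers; one mismatch would systematically drop reads
carrying two nearby alternate alleles and bias allele frequencies down),
and a unique/multi/unmapped verdict. Map quality is 37/25/15 for unique
0/1/2-mismatch hits; ties get 0 and are excluded. SAM ingestion uses the
file's own MAPQ.

Only reads with MAPQ ≥ 10 enter the pileup. A site is called when exactly
two alleles are observed, one being the reference base; the minor allele
has ≥ 3 reads; depth ≤ 4× the average (collapsed-paralogue guard); the
best MAPQ at the site is ≥ 10; and the consensus quality is ≥ 10.
Consensus quality is defined here as the Phred-scaled likelihood ratio of
a biallelic model (allele mixture at the observed proportions, per-allele
mean base-error rates) against a monoallelic-reference model, floored at
0 and capped at 60. Sites whose reference base is N (spacer runs in the
artificial chromosome) are never called. Triallelic sites and two-allele
sites lacking the reference allele are rejected and tallied. MAF is
`min(ref, alt) / (ref + alt)`; the merged MAF across populations is
count-weighted. Sites where populations disagree on the allele pair are
flagged and excluded from summaries. The depth cap uses each population's
own mean depth.

The augmented reference concatenates contigs ≥ 200 bp into one artificial
chromosome with 50 bp N spacers and an exact coordinate round-trip table.

**MAF recovery calibration.** Read counts at a site are not a simple
binomial draw from the population frequency: reads resample the pool's 50
founder haplotypes, so the variance of the alt read fraction is
`f(1−f)[1/n + (1−1/n)/50]`. The recovery tests therefore use this
two-stage normal interval (`pooled_frequency_interval`); a pure binomial
interval ignores the haplotype term and undercovers the planted
frequencies by construction.

## Panel design

Eligibility: Infinium type II allele pair (A/C, A/G, T/C, T/G — one bead
type), design score ≥ 0.6, and no other variant within ±10 bp (inclusive)
on the same chromosome. Priority is a 5 × 5 lattice, class 1 best:
source/validation level (validated with frequency data; RRL + database;
RRL novel with both group MAFs; RRL novel with one; database/legacy with
none) × MAF tier (≥ 0.4, 0.3–0.4, 0.2–0.3, 0.1–0.2, < 0.1 or absent),
where the tier MAF is the minimum over the available broiler/layer values
— a SNP is only as useful as its worst group. The lattice is configurable
because the 25 classes are a convention, not a law.

Spacing: 20 kb on macro-chromosomes, 4 kb on micro-chromosomes,
log-interpolated tiers for intermediates (larger half at ~11.7 kb,
smaller at ~6.8 kb), tracking the inverse relation between chromosome
size and recombination per Mb. Selection scrolls each chromosome with a
cursor: the window `(cursor + s/2, cursor + 3s/2]` is searched for the
best candidate by (priority class, higher mean MAF, proximity to
`cursor + s`, position); an empty window advances the cursor by `s` and
records a gap. The proximity tie-break is deliberate: with a "leftmost"
tie-break, dense equal-priority candidates would land at the window's
lower edge every step and halve the realized spacing. Add-on sets
(unplaced contigs, chr_random, mitochondrion) bypass spacing and
eligibility — they exist to cover sequence the scroll cannot reach.

## Array performance

A genotype-level stand-in replaces intensity clustering: per SNP, design
failure and cluster failure are Bernoulli draws; genotypes are
Hardy–Weinberg draws from per-breed allele frequencies. The four-class
partition is: `failed` (assay not designed); else `excluded` (cluster
review failed, all calls heterozygous — the paralogue signature — or no
calls at all); else `polymorphic` (both alleles in at least one single
breed); else `monomorphic`. Percentage conventions follow the published
table: the failed percentage is over the whole group, the other three are
over SNPs passing design. (The published failed percentage for the full
panel, 5.0, is not exactly 3164/60800 = 5.2; the passing-design
convention reproduces all four polymorphic percentages exactly, so it is
the one adopted.)

## Two-point linkage

A meiosis is informative for a marker pair when a parent is heterozygous
at both markers and the transmitted allele is resolvable at each
(homozygous offspring resolve directly; heterozygous offspring resolve
only if the other parent is homozygous). Phase is chosen per parent by
maximizing the likelihood — equivalently, folding to
`R = min(R, N − R)` — giving `theta_hat = min(R/N, 0.5)` and the
closed-form LOD `log10[θ^R (1−θ)^(N−R) / 0.5^N]` (0 at θ = 0.5). Two
simplifications are deliberate:

* AB × AB matings with AB offspring contribute no meioses (no fractional
  information), and
* when *both* parents are heterozygous at both markers, transmissions
  resolve only for double-homozygous offspring, where the two gametes are
  provably identical; the second parent's copy is a duplicate of the same
  observation and is dropped. Counting both inflates the folded
  recombinant deficit on perfectly correlated observations and produces
  spurious LOD > 4 links between unlinked markers.

Chromosome assignment requires ≥ 2 mapped markers on one chromosome (and
no other) above the LOD threshold; ambiguity yields an unassigned marker
with a conflict flag. New linkage groups are connected components of the
LOD > 4 graph among unassigned markers; singletons are not groups; labels
are assigned by descending size, then smallest member id. Ordering is
greedy two-point chaining (anchor at one end of the most distant pair,
repeatedly append the nearest remaining marker), with adjacent distances
through Kosambi `d = 25 ln[(1+2θ)/(1−2θ)]`; this is not a multipoint
order, and map spans from two-point estimates are only approximate at
small family sizes.

**Standard recovery scenario.** Two hidden chromosomes carrying 15 and 13
markers at 5 cM spacing, two families × 46 offspring (92 meioses per
parent pair at most), founder frequency 0.5 with `min_het_parents=3`.
Under these conditions the test suite requires the exact truth partition
to be recovered in ≥ 95 of 100 seeds. Without the segregation condition
roughly 6% of markers per seed have no heterozygous parent and are
unmappable, so exact-partition recovery is impossible at that rate — the
condition models marker panels chosen for high MAF, as array content is.

## Problem sizes

The default test and reproduction runs use a 240 kb genome (one 200 kb
macro-, two 20 kb micro-chromosomes), ~800 planted SNPs, four pools at
30× over the 125–200 bp fraction (~80,000 read pairs in total), and 100
replicates of the linkage scenario. These sizes keep the whole suite
under a minute of compute while leaving every statistical assertion
well-powered; all of them scale linearly if larger runs are wanted.

## Known limitations

* The mapper and caller target clean synthetic data; there is no repeat
  masking, no indel handling, no base-quality recalibration.
* Pool MAF estimation ignores unequal DNA contributions between pooled
  individuals.
* The consensus quality is a self-defined likelihood ratio, not the
  statistic of any particular legacy caller; only its ≥ 10 threshold
  semantics are relied on.
* Two-point ordering is not multipoint; published multipoint map lengths
  are not comparable targets.
* The intermediate-chromosome spacing tiers are an interpolation
  convention; per-chromosome published spacing tables were not available
  to calibrate them.
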