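# Methods

This note documents the models, parameters and design choices behind
the package, and what the synthetic data do and do not establish.

## Calling model

**Genotyping.** RES-Scanner-style callers genotype from DNA before
trusting any RNA mismatch. We use a frequency-threshold genotyper:
homozygous when the major allele holds ≥ 95% of ≥ 10 bases, het below
that, no call under 10×. Both thresholds are configurable
(`genotype_hom_fraction`, `genotype_min_depth`). A Bayesian likelihood
model would sharpen calls at marginal depth but changes nothing at the
30× depths the analyses target; the threshold form also makes the
"candidates only at homozygous positions" contract easy to audit.

**Reference adjustment** substitutes the homozygous DNA consensus into
the assembly wherever the two disagree — substitutions only, so every
sample of a species keeps one coordinate system. The change log is
written per sample. Downstream sequence-context analyses (motif
windows, codons, fold-back scans) use the first sample's adjusted
genome; with species-wide strain differences the per-sample adjusted
genomes are essentially identical, and this keeps those analyses
deterministic in the sample set.

**Standard pass.** One site per (position, transcribed strand) with
exactly one alternative base, ≥ 3 supporting reads at Q ≥ 30, level
≥ 0.05. Strand assignment is the dUTP rule — mate 2 carries the
transcript strand — hard-wired as the default with a `read2_sense`
switch for the opposite chemistry. Positions with two distinct
alternative bases are discarded outright: at p ≈ 0.001 per-base error
this costs ~2–3% sensitivity at 30× but removes a class of alignment
artifacts. Calling is per-strand independent, so a position edited on
both strands of a sense–antisense duplex yields two sites.

**Internal aligner.** Reads are ungapped by construction (the
simulator plants no indels and transcripts are genome-collinear), so
the aligner is exact k-mer seeding (k = 13) plus full-length
verification. A read with ≤ floor(L/k) − 1 mismatches always retains
an exact seed, so at L = 100 and the default mismatch cap of 4 the
aligner has no seeding blind spot. MAPQ is a uniqueness proxy: 37 for
a strictly best placement, 0 for ties — conservative in collapsed
three-letter space, where ambiguity should disqualify a read. The cap
of 4 mismatches per mate is what makes cluster-bearing molecules
(≥ 6 co-edited sites per read) fail standard alignment and flow into
the hyper path, mimicking the behavior of a stringent short-read
aligner on hyper-edited reads.

**Hyper-editing.** The three-letter scheme is generalized mechanically
to all 12 substitution types: for X→Y, mate 2 and the positive
reference collapse X→Y; mate 1 and the negative reference collapse
complement(X)→complement(Y). Orientation on each reference is
enforced as stated (positive: mate 1 reverse-complement, mate 2
direct; negative mirrored), which is exactly the geometry dUTP pairs
from +/− strand transcripts produce. Pairs scoring equally on both
references are discarded as unresolvable. Verdict thresholds are
strict inequalities (> 5% mismatch rate on the 10+10-trimmed span,
> 60% expected-type share); 5.0% and 60.0% exactly fail. Site
extraction reuses the standard caller on the hyper-read-only pileup
with support ≥ 2 and level floor 0, per the hyper-pass parameterization.

Externally produced alignments can stand in for the internal aligner at
any point: `io.read_sam` yields the same `AlignedRead` objects the
aligner emits, and `hyper.score_hyper_read` / `hyper.extract_hyper_sites`
accept them directly, so transformed alignments from another tool can be
scored and mined without the internal seeding step.

**Merging and recovery.** Supports are added where both passes find a
site. The recovery test is the upper tail of B(k, n, p) with p = 0.001
(the maximal error probability of a Q ≥ 30 base), n the
transcribed-strand RNA depth (consistent with how levels are computed
everywhere else), k the reads carrying the editome's edited base.
The BH adjustment runs over all recovery candidates within one sample
— the smallest defensible universe; it is logged so it can be audited.
The DNA-variant filter removes a site species-wide when the edited
base exceeds 10% of any sample's DNA bases (strictly greater), which
is what eliminates heterozygous SNPs that slip through single-sample
genotyping.

## Landscape, antisense, motif, recoding

* Clusters are genomic regions (strand ignored), maximal runs with
  gaps ≤ 30 and ≥ 3 members; control adenosines are depth-matched
  within ±20% on the site's transcribed strand, drawn without
  replacement, sites without an eligible control skipped.
* Editability counts transcribed adenosines per strand (base A on the
  strand, depth ≥ 2; ≥ 10 in the weighted variant, where a site
  contributes its level). Classes with zero transcribed adenosines
  report a missing density, not zero.
* Divergence bins: transcribed repeat loci (≥ 50 nt at ≥ 2×) sorted by
  realized divergence, ties broken by coordinate, ten equal-count bins
  (`numpy.array_split`); fewer than ten loci is an error instructing a
  smaller bin count.
* dsRNA-forming potential and the fold-back exclusion share one
  reverse-complement local aligner: seed-and-extend (k = 13), ungapped
  X-drop extension (match +1, mismatch −2, drop 20), thresholds applied
  exactly (identity ≥ 80%, length ≥ 50 nt — or ≥ 20 nt for the
  fold-back exclusion — and the aligned query region spanning the
  site). Ungapped seeding means copies diverged well past the 80%
  threshold can lack an exact 13-mer and be missed; at the ≤ 5%
  per-copy divergence of the inverted-pair analyses the seed
  probability is ≈ 1. Ties break to the leftmost target position.
  Windows clipped at contig ends keep the site and renormalize
  fractional criteria to the clipped length.
* "Peak depth" in the antisense cascade is the mode of the
  covered-position DNA depth histogram (configurable to median);
  exclusion requires depth strictly above 3× the peak.
* The motif background is every transcribed (≥ 2×) unedited adenosine
  within ±50 nt of an edited one, deduplicated by position; per-cell
  two-sided exact binomial tests against the background frequency are
  BH-corrected across the 40 non-center cells. Cells with background
  frequency 0 or 1 are skipped. The 40-cell frequency-difference
  vector (position-major, A<C<G<T) is exported for external
  ordination; the ordination itself is out of scope.
* Recoding filters are pure predicates of (site, species editome), so
  the cascade is order-independent by construction: hyper-region
  exclusion (> 10 same-type sites, gaps ≤ 20, computed on the pooled
  species editome), mixed-type window (±12 nt — the odd 25-nt window),
  recurrence (≥ 2 samples, summed depth ≥ 10, mean level ≥ 0.1).
  Shared events match alignment columns and amino-acid changes on
  caller-provided protein MSAs; a designated sibling-species pair can
  be excluded from pair-only events.

## The simulator

The generator emulates: a uniform-random genome; repeat families with
per-copy substitution at the family rate (realized divergence stored
per copy), a tunable fraction arranged as nearby (≤ ~500 nt) inverted
pairs; intron-containing genes with clean ORFs, half on each strand,
some arranged as antiparallel pairs overlapping in their 3′UTRs;
heterozygous SNPs (50% allele fraction) and homozygous strain
differences; dUTP paired reads with i.i.d. errors at 0.001 on Q40
bases plus a 2% fraction of Q15 bases erring at 10% (exercising the
quality floor); and planted A-to-I edits in five categories. Cluster
and hyper-region edits are correlated per molecule — an editing
molecule carries all covered member sites — which is what produces
genuinely unalignable hyper-edited reads. Edits on minus-strand
transcripts are written as T→C in reference coordinates and must come
back out as A-to-G on strand "−". A 0.8 probability of a 5′ U
neighbor is imposed when drawing edit positions, emulating the ADAR
preference.

Default study conditions (the reference recipe): 200-kb genome, 3
samples, 30× DNA and RNA, 100-nt reads at 260 ± 25 nt fragments, 300
het SNPs, 100 strain differences, 200 isolated sites at levels
0.2–0.8, 50 six-site clusters (span ≤ 60 nt, molecule-level 0.7), 4
hyper regions (150 nt, per-read A fraction 0.35), 12 recoding sites, 3
antisense pairs with an alternating-strand chain of 8 edits per
overlap. Two dedicated recipes define the divergence-trend analysis
(five repeat families spanning divergence 0.02–0.26, site weight
∝ exp(−10·divergence)) and the inverted-pair-rich / repeat-free
genomes of the dsRNA-potential analysis. Problem sizes were chosen so
a full reference run is a couple of minutes on one core while keeping
every per-criterion count (300 cluster members, ~470 evaluable
isolated site-sample pairs, 400 variant positions) large enough for
stable fractions.

What passing on synthetic data does **not** show: robustness to
indels, splicing and split reads (transcripts are genome-collinear by
design), GC- and position-dependent error profiles, PCR duplicates,
mappability structure of real repeat landscapes, or cross-species
generalization of any biological observation. Results on real data
depend on upstream aligner and annotation quality in ways the
simulator deliberately does not model.

## Numerical and engineering choices

* Coordinates are 0-based half-open internally; every emitted table is
  1-based inclusive.
* Binomial tails come from `scipy.stats.binom.sf` (verified against
  exact rational arithmetic to 1e−12 relative error in the tests); BH
  from `statsmodels`; Fisher tests from `scipy` (verified against
  hypergeometric enumeration).
* All randomness flows through `numpy.random.default_rng` seeded from
  recipe/config seeds; no global RNG state. Identical seeds reproduce
  all outputs byte for byte; tie-breaks (alignment placement, bin
  assignment, control sampling) are deterministic.
* Antisense planting keeps sites ≥ 120 nt from both transcripts' 3′
  ends because contained-fragment sampling ramps coverage down over
  the final fragment length; sites inside that ramp would be
  undetectable at any calling threshold rather than informative.
* N bases never count as matches, never contribute to pileups, and
  collapse no k-mers (windows containing N are unseeded).

## Known limitations

Gapped alignment and BAM/CRAM beyond pysam's text-SAM handling are out
of scope; the aligner is a desk-scale instrument, not a BWA
replacement. The genotyper does not model contamination or ploidy
> 2. Recovery assumes the editome's substitution type at a position;
a sample supporting a different base is simply not recovered there.
UTR annotation, repeat annotation, orthology and protein alignment are
consumed as inputs, never computed.
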