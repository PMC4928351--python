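# Methods

This note documents the models and procedures `ahekit` implements, the
parameters that matter, what the synthetic data do and do not emulate, and
the numerical choices made where the design was genuinely open.

## The workflow

Anchored hybrid enrichment capture produces paired-end reads concentrated
on conserved anchor regions and tapering into variable flanks. The package
processes them in five stages — merging, assembly, orthology, trimming,
concatenation — each behind its own module, with a probe-design module for
the upstream kit-design rules and a simulation module that plants ground
truth.

### Read merging (`read_merge`)

For a pair (r₁, r₂), every overlap degree o ∈ 1…min(|r₁|,|r₂|) between the
suffix of r₁ and the prefix of reverse-complemented r₂ is scored by the
one-sided binomial tail P(X ≥ m | o, p₀) with null match probability
p₀ = 0.25 (uniform bases; configurable). The minimal-p overlap wins, ties
going to the longer overlap (the physically larger explanation); the pair
merges iff p < α = 10⁻¹⁰. Within the overlap, matching bases keep the base
with quality min(q₁+q₂, 93) (cap keeps Phred+33 printable); mismatches take
the higher-quality base with quality |q₁−q₂|; N never wins a mismatch. Only
"innie" overlaps (fragment ≥ read length) are searched by default. No
minimum absolute overlap is imposed beyond the p-value criterion: at
α = 10⁻¹⁰ the shortest mergeable perfect overlap is 17 bp, and the
Monte-Carlo false-merge rate for unrelated 150 bp pairs is below 10⁻³.

### Assembly (`assembly`)

The reference library holds, per locus, the majority consensus of the
design alignment and an index of spaced 20-mers (20 positions at every
third base, 58 bp span) anchored where all 20 sampled columns have modal
base frequency ≥ 0.9, thinned to one anchor per 10 bp. When a simulated
locus offers fewer than 3 such anchors the threshold relaxes in 0.1 steps
(floor 0.5) for that locus: an unmappable locus is lost wholesale, and real
probe regions are conserved by construction, so the relaxation is a
library-construction safeguard, not part of the matching statistics.

Recruitment interleaves two mechanisms until a full pass adds no read:
a read with ≥ 17/20 positional matches to an indexed spaced k-mer is
confirmed by gap-free alignment against the locus reference (mapped iff
≥ 55 matches within the best 100 consecutive aligned bases, over all
offsets, ties to the smallest offset); independently, a read sharing one
exact 60-mer with an already-placed read joins at the offset implied by the
k-mer positions (majority vote across shared 60-mers). The second mechanism
is what walks assemblies out of the probe region into the flanks. Both read
orientations are tried; reads are stored in assembled orientation.

Placed reads are partitioned per locus by union-find over 60-mers, two
60-mers joining when they co-occur in ≥ 2 reads; a read follows the
component holding the majority of its 60-mers (ties to the larger
component), and reads sharing no component become singletons. Candidate
read pairs are enumerated among offset-overlapping reads only — reads with
disjoint spans can share a 60-mer only through an exact intra-locus 60 bp
repeat, which the simulation makes negligible.

Offsets are then refined greedily: per read, shifts within ±3 are always
tried, and single-gap insertions (≤ 1 per read) are tried only when the
read agrees with the column majority at < 95% of its bases; a variant is
accepted only if it strictly increases the read's agreement with the rest
of the cluster, so total pairwise agreement is monotone and the passes
reach a fixed point.

Consensus calling is per column with coverage n and majority count m: the
majority base is called when m = n or when P(X ≥ n−m | n, p_err) ≥ α with
p_err = 0.1, α = 0.05 (polymorphism explainable as sequencing error);
otherwise the IUPAC code over the majority base plus every base whose own
count is individually significant under the same tail test. Ties in the
majority break to the lexicographically smaller base, deterministically.
Sites with coverage < 5 are lowercased (soft-masked); zero-coverage
interior columns become `n`. Counts are unweighted — the binomial model
treats reads as exchangeable draws, so merged-read qualities do not enter.

### Orthology (`orthology`)

Consensus sequences from clusters with < 10 reads are removed; in the
simulation every contaminant read is an independent uniform random
sequence, so contaminant clusters are essentially singletons and this
filter removes them all. Survivors are grouped by locus into homolog sets.
The distance between two homologs is 1 − Jaccard similarity of their
pooled 20-mer sets (consecutive plus spaced every-third-base; case-folded,
since lowercase encodes coverage, not doubt about the base; spaced k-mers
are tagged so they only match spaced k-mers). Clustering agglomerates pairs
in ascending distance (ties in lexicographic id order, making the result
invariant to input order); a merge whose union would contain two sequences
from one individual is skipped outright — this is the paralog guard — and
pairs with no shared k-mer (distance 1.0) never join, since joining on zero
evidence is indefensible. Clusters below 50% species occupancy are dropped
after clustering completes.

Paralog separation upstream is probabilistic: two copies at divergence d
share an identical ≥ 60 bp run with probability ≈ 1−exp(−L·d·(1−d)⁶⁰) (for
L = 700, d = 0.1: ≈ 0.12), and such a run bridges the 60-mer graph, giving
one blended, IUPAC-rich consensus instead of two. The orthology-level
per-individual constraint holds regardless.

### Alignment and trimming (`trim_align`)

Each ortholog set is aligned with MAFFT using `--genafpair
--maxiterate 1000`; the invocation is logged verbatim. When no aligner
executable is available a bundled center-star progressive aligner (global
pairwise alignments merged once-a-gap-always-a-gap) stands in; it is a
testing convenience, not a MAFFT replacement.

Trimming is three steps in order: (1) a column is "conserved" when its
modal non-gap character exceeds 40% of the sequences (strict; denominator
is all rows, all-gap columns never conserved); (2) per sequence, windows of
20 of its own (non-gap, non-masked) positions containing < 10 stable sites
are masked to `?`, where a site is stable iff its column is conserved and
the row matches the modal character (IUPAC codes match when the modal base
is a member — heterozygous-looking but correct sites should not be masked);
(3) columns with < 12 characters outside {`-`,`?`} are removed. One
application of the three steps is not idempotent — masking lowers modal
counts and column removal rejoins window coordinates — so `trim_alignment`
repeats the three-step round until nothing changes. Masked cells and
removed columns grow monotonically, so the iteration terminates;
re-application is then a no-op, columns never increase, and an alignment of
identical rows passes through untouched.

The absolute cutoff of 12 unmasked bases presumes a matrix of ~33 taxa
(~36%). The pipeline therefore scales it to the simulated taxon count,
`min(12, max(2, round(0.36·n_taxa)))`, while the module default remains 12;
with 8 taxa the absolute value would delete every column.

### Supermatrix (`supermatrix`)

Loci concatenate in sorted order; taxa absent from a locus are padded with
`?`; the partition table uses the RAxML dialect `DNA, locus = a-b`
(1-based, inclusive). Lowercase consensus characters are uppercased on
export, since phylogenetic formats carry no case semantics. A site is
parsimony-informative iff ≥ 2 unambiguous states each occur in ≥ 2 taxa
(IUPAC ambiguities count as missing). The sanity tree is neighbor-joining
(scikit-bio) on p-distances with pairwise deletion; a taxon pair with zero
comparable sites is an error naming the pair; negative NJ branch lengths
are clamped to zero. Maximum-likelihood search, partitioned model fitting
and bootstrapping are out of scope by design — the package emits the inputs
an ML tool consumes.

## The synthetic data generator (`simulate`)

The generator emulates a capture experiment with planted truth:

- **Species tree** — coalescent-style random joins rescaled to a
  root-to-tip height of `tree_height` expected substitutions/site
  (default 0.2, a deep-but-alignable divergence typical of family-level
  datasets). Ultrametric, binary, reproducible from the seed.
- **Loci** — `n_loci` regions of `flank_len + anchor_len + flank_len`
  (defaults 200 + 300 + 200 = 700 bp, matching the anchor-target geometry
  of typical AHE loci) evolved site-independently under Jukes–Cantor
  (HKY optional, κ configurable) with region rate multipliers
  `anchor_rate_scale` = 0.3 < `flank_rate_scale` = 1.5 — the conserved-core
  / variable-flank structure enrichment exploits. No indels are simulated.
- **Reads** — fragments uniform over 150–350 bp (the sonication target
  range of the emulated protocol) at uniform positions, never spanning
  loci; PE150 reads from each end; per-base errors Bernoulli
  (`base_error_rate`, default 0.003 ≈ Phred 25, a conservative HiSeq-class
  rate); quality 40 for correct calls and uniform 2–20 for errors, so
  quality-aware merging is testable. `coverage_mean` is per-base depth
  (default 20×); the fragment count per locus per individual is
  depth · locus_len / mean_fragment_len.
- **Contaminants** — `contam_fraction` (default 1%) of read pairs drawn
  from independent uniform random sequences: maximally k-mer-disjoint from
  targets and from each other, so they test the low-coverage filter rather
  than the mapper.
- **Duplications** — `dup_loci` plants a second copy of a locus in a taxon
  at `dup_divergence` (default 10%), sequenced at full depth alongside the
  original.

Not emulated: indel evolution, PCR duplicates, adapter read-through,
quality-by-cycle decay, GC-biased coverage, heterozygosity, and real
cross-species contamination (which shares k-mers with targets). Passing
planted-truth tests therefore demonstrates the correctness of the
algorithms under the stated model, not robustness to every artifact of
real libraries.

## Problem sizes and determinism

The standard end-to-end configuration used by the test suite and the
acceptance script is 8 taxa × 30 loci at 20× depth, 0.3% base error and 1%
contaminants (~17,000 read pairs), which runs in about a minute on one
core; the paralog-safety experiment uses 6 taxa × 2 loci per seed. All
randomness flows from a single integer seed through
`numpy.random.default_rng`; identical configurations produce byte-identical
FASTQ output. Binomial tails come from `scipy.stats.binom.sf` and are
checked in the tests against explicit `math.comb` summations; agreement is
required to 10⁻⁹ relative.

## Known limitations

- The 60-mer bridge effect above means closely spaced paralogs (< ~5%
  divergence) usually assemble as one ambiguity-rich consensus; the
  package reports them as such rather than attempting haplotype phasing.
- `find_exon_boundaries` requires exact 40-mer matches, so boundaries in
  highly diverged transcript/genome pairs go undetected (reported as
  unknown runs).
- The high-copy 15-mer census is exhaustive and memory-resident; it is
  meant for desk-scale genomes and tests, not multi-gigabase scans.
- The center-star fallback aligner is adequate for the near-identical
  ortholog sets the pipeline produces, but it is no substitute for MAFFT
  on deeply diverged input.
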