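# Methods

## The problem

A tumor sample is a mixture: a fraction *t* of its cells are tumor cells
with an aberrant genome, the rest are diploid normal cells.
Allele-specific copy number analysis (ASCNA) aims to recover, for every
genomic segment, the integer total copy number *n* and the minor-allele
copy number *m* (copies of the less abundant homolog, *m* ≤ ⌊*n*/2⌋) of
the tumor cells, together with two sample-level quantities: the average
tumor ploidy *P* (length-weighted mean of *n*) and the tumor cell
fraction *t* (purity).  The inputs are whole-genome sequencing read
depth and the allele read counts of constitutively heterozygous SNPs.

## Signal model

Read depth is proportional to local DNA content.  At purity *t*, a
region of total copy number *n* contributes DNA in proportion to
*t·n + 2(1−t)*, so after normalization the coverage of a segment is
linear in *n*.  At a heterozygous SNP where the allele sits on a
homolog present in *c* tumor copies, the expected allele read fraction
is

    f = (t·c + (1−t)) / (t·n + 2(1−t)).

Because the data are unphased, each segment summarizes its SNPs with the
allelic imbalance ratio

    AI = (Σ high − Σ low) / Σ high,

where `high`/`low` are each SNP's larger/smaller allele count and the
sums run over all heterozygous SNPs in the segment — summing reads
weights each SNP by its coverage.  AI is 0 for perfect balance and 1
for complete loss of heterozygosity (LOH).  In the (coverage, AI) plane
the (n, m) states form a lattice of clusters whose geometry encodes
ploidy and purity.

## Pipeline

1. **Window counts.** Reads are counted into fixed 200-bp windows by
   their leftmost aligned base.  Duplicates, secondary and supplementary
   alignments are excluded; mapping quality floor 20.  (These filters
   are field-standard defaults for depth analysis; the counting
   semantics conserve reads.)
2. **GC normalization.** Windows are grouped by GC fraction in
   1-percentage-point groups and each count is divided by its group
   mean.  This removes the smooth, platform-dependent GC–coverage
   relationship without assuming its shape.  Groups with fewer than 100
   windows fall back to the global mean.
3. **Positional normalization.** The GC-normalized counts are divided by
   a reference profile built from one or more diploid genomes (each
   GC-normalized, scaled to mean 1, averaged per window; windows below
   0.1 are masked).  A patient-matched normal can serve as a
   single-sample reference when its coverage supports it; at very low
   normal coverage a well-covered diploid panel is the appropriate
   denominator, with the matched normal reserved for heterozygous-SNP
   identification.
4. **Binning.** Per-window ratios are averaged into fixed 10-kb bins
   laid out from each arm's start, so no bin straddles a centromere.  A
   bin needs at least 50% of its windows present, else it is missing.
   The genome-wide median of non-missing bins is rescaled to 1 (median,
   not mean, so focal amplifications do not move the anchor).
5. **Segmentation.** Each arm is segmented by circular binary
   segmentation on the untransformed ratio (the calling model is linear
   in coverage, so no log transform).  The best circular arc maximizes
   the two-sample t statistic between the bins inside and outside the
   arc; a split is accepted when the permutation p-value of the maximum
   is below alpha = 0.01 (10,000 permutations).  Two shortcuts keep this
   tractable without changing any decision that is not already certain:
   a conservative Bonferroni bound over all arcs (t tail, L−2 df)
   resolves clearly significant cases, and permutation stops early once
   20 exceedances prove p ≥ alpha.  Ties in the maximum break toward the
   leftmost arc, and permutations are generator-seeded, so decisions are
   deterministic.  After recursion, adjacent segments whose means differ
   by less than 3 robust noise SDs (MAD of successive differences,
   divided by √2) are re-merged; real copy steps are ≥ 5 SDs in the
   regimes of interest, so this only removes low-amplitude spurious
   splits.  Arms with fewer than 5 usable bins become one
   low-confidence segment.  Missing bins are spanned; segment
   coordinates snap to the outermost member bins.
6. **Imbalance.** Heterozygous SNPs are selected from the matched normal
   (depth ≥ 5, minor fraction ≥ 0.2) or, without one, from known
   polymorphic positions where the tumor shows both alleles (the latter
   biases AI down in LOH regions at low coverage and is the fallback,
   not the preference).  Segments with fewer than 10 SNPs get a missing
   AI — per-SNP ratios are sampling noise.
7. **Calling.** See below.

## Calling model and anchors

Calling needs four anchors, the quantities an analyst reads off the
scatter plot: the coverage step per copy Δobs, the coverage of the
copy-2 cluster, and the AI of the balanced-diploid (2m1) and
diploid-LOH (2m0) clusters.  Expected coverage of (n, m) is linear:
`cn2_ratio + (n−2)·Δobs`.

Expected AI needs a bias model.  At per-SNP depth *d* the allele counts
are Poisson-thinned and independent, so the allele-count difference
A − B has mean d(2f − 1) and variance d; |A − B| is then approximately
folded normal, and the pooled segment AI is

    AI(n, m) = 2·E|A − B| / (d + E|A − B|).

This explains the well-known positive bias of the max/min estimator for
balanced states (AI of a 2m1 segment is ≈ √(2/(π d))·2 rather than 0)
and its depth dependence.  The model has two free parameters — a noise
scale κ multiplying √d (absorbing overdispersion relative to the pure
Poisson-binomial account) and the implied purity — and both are
calibrated in closed form / by 1-D root-finding so the two AI anchors
are reproduced *exactly*.  Expected AI of every other state follows
from the same formula with *f* and *d* scaled by that state's DNA
content.  When no anchor depth is supplied the model degenerates to the
ideal (infinite-depth) lattice

    ideal_AI(n, m) = t·(n − 2m) / (t·(n − m) + (1 − t)),

reached through a purely algebraic anchor interpolation.  A linear
interpolation between the anchors was considered and rejected: the
folded-normal bias is strongly nonlinear in the DNA-level imbalance, and
at 4× equivalent coverage the linear version systematically misassigns
minor copy numbers (e.g. 4m1 → 4m2 even in pure tumor); the depth-aware
model keeps those states separated down to 30% tumor content.

Each segment is assigned the state minimizing

    d² = ((ratio − e_ratio)/Δobs)² + ((AI − e_AI)/s_AI)²,

with s_AI half the 2m1→2m0 span — each axis scaled by its natural unit.
Segments without AI match on coverage alone and report a missing minor
copy number; ties break toward lower *n*, then higher *m*.  The
continuous coverage-implied copy number is reported alongside for
heterogeneous (chromothripsis-like) regions where integers are the
wrong description; calls are capped at max_cn = 8 with the continuous
value carrying the information above it.

## Purity and ploidy

With calls in hand: ploidy *P* is the length-weighted mean of *n*; the
expected per-copy step in a pure tumor is Δexp = 1/P; the tumor DNA
fraction is DNAfrac = Δobs/Δexp after moving Δobs to the scale where
the genome-average normalized coverage is 1 (division by the
length-weighted mean coverage of the called genome — the pipeline's
median scaling anchors the modal state at 1, not the mean, and the two
differ in aneuploid genomes); and inverting the two-population mixture
(normal cells diploid) gives

    purity = 1 / (1 + (P/2)·(1/DNAfrac − 1)).

The forward mixture DNAfrac = tP/(tP + 2(1−t)) and this inversion are
exact inverses (verified to 1e-12 over a 1,000-point grid).

## Synthetic data

The simulator emulates exactly the signal model above: window counts
Poisson (optionally negative-binomial overdispersed) with mean
`coverage · bias(gc) · (t·n + 2(1−t))/2`, a smooth synthetic GC track
with a quadratic bias bump peaking at GC 0.45 (range [0.6, 1.2]) so GC
normalization has real work to do, and het SNPs at 0.5/kb with Poisson
depth and binomial allele counts, the allele landing on the major or
minor homolog with probability 1/2 (unphased data).  Non-integer total
copy numbers are accepted per segment and read as mean DNA content of a
heterogeneous region.

The default study genome is a fixed ~300 Mb layout: six 50-Mb
chromosomes, segments of 7–25 Mb covering the states
{1m0, 2m0, 2m1, 3m0, 3m1, 4m1, 4m2}, balanced-diploid majority
(184/300 Mb) so the genome median anchors at copy 2, true average
ploidy 682/300 ≈ 2.273.  Diploid-LOH regions sit at arm boundaries —
they have the same coverage as balanced-diploid regions, so
coverage-driven segmentation can only separate them at a coverage
boundary; this is a property of the method, not of the simulator.

In-silico dilution thins tumor and normal reads binomially so the
expected tumor:normal read ratio is t·P : 2(1−t) at the tumor sample's
original coverage (the read-selection probability implied by the
mixture model; the shallow-coverage benchmark uses 4× tumor / 5× normal
with a well-covered diploid reference).

What the simulator does *not* model: mappability and positional
artifacts beyond GC (the positional reference is therefore exercised
only as a pass-through denominator), sequencing error, subclonal
mixtures, and read-level detail (no FASTQ).  Passing recovery tests on
it therefore demonstrates the estimator chain and its calibration, not
robustness to artifacts absent from the generative model.

## Benchmark protocol

Calls ≥ 1 Mb are matched to gold segments when a single gold segment
covers ≥ 75% of the call (single-segment, not pooled, overlap); exact
total-and-minor matching defines per-state tp/fn/fp/tn over matched
pairs (each pair contributes exactly one cell per state), with
sensitivity 100·tp/(tp+fn) and specificity 100·tn/(tn+fp) to one
decimal.  An exclusion list parameter removes chromosomes known to
differ between sources.  Two called genomes are compared base-pair-wise
by gain/loss/unchanged status relative to each sample's own neutral
copy number.  On synthetic data the anchors are calibrated from
truth-labeled segments (the stand-in for reading clusters off the
plot): Δobs and the cn-2 coverage from a length-weighted linear fit of
segment coverage on true *n*, AI anchors from the pooled ratios of the
labeled (2,1)/(2,0) clusters, anchor depth from the copy-2 segments.

Problem sizes used by the shipped tests and the acceptance script: the
300 Mb default genome (1.5 M windows, ~30 k bins, ~150 k SNPs) at 30×
for recovery at purities 1.0/0.7/0.5; the same genome at 4×/5× for the
dilution series at purities 1.0/0.7/0.3; 20 seeded piecewise-constant
arms for breakpoint localization; 1,000-case oracles for the imbalance
ratio and the mixture round trip.

## Numerical choices and edge cases

- Segments with variance at float-rounding scale (≤ 1e-10 relative) are
  treated as constant in the CBS scan.
- GC groups with zero mean, reference windows below the 0.1 floor, bins
  below the 50% window quorum, and segments below the 10-SNP quorum all
  propagate as missing, never as zero.
- An empty heterozygous-SNP set gives an undefined AI (a missing ratio
  and a balanced ratio mean different things).
- The anchor-inversion root-find is monotone on [0, 1] and clamped at
  the boundaries (an AI anchor at 1 with noise implies purity 1).
- Dilution to a purity the normal sample cannot support fails with the
  maximum achievable purity in the message.

## Known limitations

- LOH regions coverage-identical to their neighbors are only delimited
  by coverage boundaries; a segment blending 2m0 and 2m1 reports the
  blended AI (haplotype-aware assignment is out of scope).
- Tumor-only heterozygous-SNP selection requires both alleles observed
  and so under-reports AI in LOH regions at low coverage.
- The caller assumes clonal integer states; subclonal mixtures surface
  as non-integer continuous copy numbers and larger assignment
  distances, not as explicit subclone fractions.
- No mappability, replication-timing or wave correction; the positional
  reference is the only defense against shared positional bias.
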