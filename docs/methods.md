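# Methods

## The measurement model

E/L Repli-seq sorts BrdU-labeled cells into early-S and late-S fractions;
per-bin read counts from each fraction quantify replication timing as
RT = log2(E/L).  In an F1 hybrid line, SNP-phased reads give one count
track per allele, so a heterozygous deletion and its unmodified homolog
are measured in the same library.  This package operates strictly
downstream of alignment and phasing: its inputs are binned per-allele
early/late counts (50 kb bins by default), and everything upstream
(trimming, alignment, haplotype splitting, duplicate removal) is out of
scope.

Coordinates are 0-based half-open throughout; bin *i* of a grid with bin
size *b* covers [i·b, (i+1)·b), and a trailing partial bin is dropped.
Two bin-selection rules are used deliberately: *any-overlap* (≥ 1 bp) for
masking and zeroing — a bin touched by a deletion has corrupted counts —
and *midpoint-in-region* for value aggregation (area, domain means, gene
bodies), which avoids double-counting a boundary bin in adjacent regions.

## Processing pipeline

Order: log2(E/L) → per-sample scaling → quantile normalization → loess →
replicate averaging.

- **log2 ratio.**  Default pseudocount 0; bins with zero total count
  (deletion footprints, gaps) are missing regardless of pseudocount — a
  zero total is absence of sequence, not an extreme ratio.
- **Scaling.**  Genome-wide z-score per sample (mean 0, sample sd 1).
  The upstream convention for "scaling" is not fully standardized; the
  z-score is chosen because it makes samples comparable before
  rank-mapping and is idempotent.  With the default simulated landscape
  (sd 1 in log2 units) it is close to the identity.
- **Quantile normalization.**  Rank-mean (preprocessCore-style): each
  track's rank-r value is replaced by the across-track mean of rank-r
  values; ties receive the mean of their tied target slots.  Computed on
  the intersection of bins non-missing in every sample — rank maps need
  complete vectors — and bins outside the intersection are missing in all
  outputs.  Consequence: a bin deleted on one allele is excluded from all
  samples of the run, which is also the comparison one wants (no
  one-sided values at deleted bins).  It is hand-written (no installed
  package provides it) and tested against a brute-force oracle including
  tie cases.
- **Loess.**  Tricube-weighted locally linear regression per chromosome
  (statsmodels lowess; iterations 0, i.e. no robustness reweighting,
  matching the default Gaussian-family loess).  The 300 kb window is
  expressed as the equivalent neighbor fraction of the chromosome's
  non-missing bins; the tricube support extends one bin past window/2 so
  the bins at the window edge carry strictly positive weight (tricube
  vanishes at its support boundary).  Degree is fixed at 1 — local linear
  fits reproduce linear trends exactly and are the standard default; a
  degree-2 option was considered and rejected to keep the smoother on the
  established implementation.  Missing bins are excluded from fits and
  stay missing; chromosomes with < 3 usable bins are left unsmoothed with
  a warning.
- **Averaging.**  Nan-aware per-bin mean across replicates; a bin is
  missing only where all inputs are missing.

## The delay statistic

ΔRT = deletion − control per bin, on the replicate-averaged smoothed
profiles.  ∆area over a query region is the trapezoidal integral with x
in bin-index units (one 50 kb bin = one unit): a constant c over k+1 bins
integrates to c·k, and a 2 Mb domain spans ~40 units.  Bin units, rather
than bp or Mb, put |∆area| on the scale of tens for domain-size delays of
1–2 log2 units.  Missing bins at region edges are trimmed; interior
gaps are bridged linearly (verified against a refined-grid trapezoid
oracle to < 1e-9).

The null model asks how large |∆area| gets from allele-to-allele
fluctuation alone: n regions of exactly the query's length are sampled
with replacement, uniformly over all valid start positions genome-wide
(chromosomes weighted by valid-start counts), rejecting regions that
overlap the blacklist by ≥ 1 bp or contain > 20 % missing bins (the
threshold is configurable; areas need adequate support).  Null areas are
computed from the same clone's genome-wide ΔRT curve.  The empirical
p-value uses the add-one correction, so p ∈ [1/(n+1), 1] and is never 0.

Directionality: the delay test is one-sided in the negative direction
(deletion later ⇒ lower log2(E/L) ⇒ negative area).  The ΔΔRT test —
area of ΔRT₁ − ΔRT₂ over the query, null from the same difference curve —
is two-sided, since "do these two deletions delay RT equivalently?" is
directionless.  Both conventions are arguments, not hard-coded.

Clones with homozygous deletions have no internal control; their control
curve is the nan-aware average of all wild-type allele profiles in the
run, and the result records `control_mode="aggregate"`.

Defaults: n = 10,000 null regions, α = 0.05.  Tests and the acceptance
script use n = 1,000 as a documented scaled-down setting; at n = 1,000
the smallest attainable p is 1/1001 ≈ 0.001.

## Synthetic data: what it emulates, what it does not

The generator mimics the *structure* of a two-allele Repli-seq experiment:

- **Landscape.**  A stationary Gaussian random field per chromosome
  (white noise circularly convolved with a Gaussian kernel), with
  correlation length 400 kb — the scale of mammalian replication domains
  — and sd 1.0 in log2(E/L) units, matching the few-log2-unit dynamic
  range of real RT profiles.  The kernel sd is length_scale/√2 so the
  *field's* autocorrelation is exp(−d²/(2·length_scale²)).  Both alleles
  share the landscape, and clones of the same cell line share it too
  (`seed` draws the landscape, `noise_seed` the sequencing noise): this
  matters for ΔΔRT calibration, because per-clone normalization of
  unrelated landscapes would rescale equal delays unequally.
- **Allele effects.**  The deletion allele is shifted by −δ over the
  query domain and by per-region offsets over blacklist regions
  (emulating loci with intrinsic allele-specific RT).  Deletion
  footprints zero both fractions on the deleted allele, mimicking
  missing sequence.
- **Counts.**  Per bin, total N ~ Poisson(depth) split
  Binomial(N, p) with p = 2^rt/(1+2^rt), so log2(E/L) has mean rt at
  high depth.  No well-established noise model exists for binned
  Repli-seq counts; this
  binomial-logit choice is a stand-in whose first moment is exact, with
  an optional overdispersion multiplier (default 1) for robustness
  experiments.  Not modeled: GC/mappability bias, SNP density variation,
  read-level effects, replicate batch effects.
- **Transcription.**  1 kb gene-body coverage, Normal(e_g, cv·e_g)
  truncated at 0, zero outside genes.  No strand, splicing or intronic
  signal structure.

Default fixture (the conditions under which all calibration and power
figures are quoted): 3 chromosomes × 60 Mb, 50 kb bins, one 2 Mb query
domain, two ~2 Mb blacklist regions (offsets ±0.8) on other chromosomes,
depth 2,000 reads/bin/fraction, 2 replicates per allele.  The gene set is
one 1 Mb gene plus two short genes inside the query domain.  A 150 kb
deletion footprint is added (opt-in) for missing-data and
deletion-detection tests.  Passing tests on this fixture demonstrate the
statistical machinery is correct and calibrated under the stated noise
model; they do not certify behavior under real-data artifacts the
generator omits (mappability structure, phasing errors, batch effects).

## Companion quantifications

- **Bru-seq.**  RPM normalization (value × 10⁶ / library size); gene-body
  signal is the nan-aware mean over 1 kb bins with midpoints in the body;
  expression ratio is deletion-allele signal over the average of all
  control alleles, NaN (with warning) when the control is zero.
  Domain-total signal sums mean × body length over genes — i.e. restricted
  to gene bodies, the quantity actually measured by gene-body averaging.
- **Peak overlap.**  Percentage of a factor's datasets with ≥ 1 peak
  overlapping a site by ≥ 1 bp; multiple peaks from one dataset count
  once.  No minimum-overlap fraction is imposed.
- **Hemizygous-deletion detection.**  Maximal runs of ≥ min_bins
  (default 2) consecutive bins with one allele ≤ ratio_floor
  (default 0.05) times the other; a run is reported only if the retained
  allele's mean coverage over the run reaches its genome-wide 10th
  percentile, which suppresses shared unmappable gaps.  The gate is
  applied at run level because a per-bin percentile test would, by
  construction, drop ~10 % of perfectly covered bins and fragment true
  footprints.  Exact bin-level recovery is therefore typical but not
  guaranteed — a short run's mean can dip below the genome-wide quantile
  by chance.

## Numerical and degenerate-input policy

Invalid arguments raise ValueError; statistically unusable inputs
(constant track to scale, < 2 usable bins for an area, all-missing
domain) raise DegenerateDataError; impossible null sampling (no valid
placement, or > 10⁶ consecutive rejections) raises
SamplingInfeasibleError.  Single-sample runs skip quantile normalization
with a warning.  All randomness flows through numpy Generators derived
from explicit seeds via SeedSequence spawn keys, so each stage is
independently reproducible and whole datasets are bitwise-deterministic.

## Known limitations

- The scaling transform and the joint-vs-pairwise scope of quantile
  normalization upstream are conventions chosen here (z-score; joint
  across the run), not uniquely determined by the assay.
- The null treats the query like any other region of the ΔRT curve;
  regions overlapping the query itself are not excluded, so under a very
  large true delay a handful of null samples near the query slightly
  inflate the null tail (conservative).
- Area is computed on the replicate-averaged curve, not averaged over
  per-replicate areas (the two differ only through missing-data
  patterns).
- No multiple-testing correction across clones is provided; p-values are
  per-test empirical values.
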