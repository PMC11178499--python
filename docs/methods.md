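# Methods

`petdiff` implements a suite of differential statistics for chromatin
architecture read out from paired-end-tag (PET) contact data — Hi-C and
protein-directed HiChIP — between two biological conditions, together
with a seeded synthetic generator that provides ground truth for
validating every statistic at desk scale. This note documents the models,
the parameters that matter, what the simulation does and does not
emulate, and the numerical choices.

## Data model and conventions

A PET is a pair of genomic point positions (0-based) representing one
proximity-ligation contact. PETs are stored canonically with
(chrom1, pos1) ≤ (chrom2, pos2). Bins are half-open
`[k·bin_size, (k+1)·bin_size)`. All analyses here are cis
(intra-chromosomal); trans PETs are parsed, counted and excluded. Binned
contact matrices are symmetric sparse CSR: each PET increments M[i,j]
and M[j,i] once (the diagonal once). Resolutions in use: 100 kb
(compartments), 5 kb (virtual 4C), 1 kb (viewpoint enrichment).

Sequencing-depth asymmetry is handled by equal down-sampling: replicate
PET sets are combined per condition and both pools are sampled without
replacement down to the common minimum before any between-condition
matrix analysis. TAD enrichment scores are ratios and therefore nearly
depth-invariant, but the comparison still equalizes depth by default so
that the intra/inter counts share sampling variance structure across
columns; this can be switched off.

## Contact-distance decomposition

The distance density module histograms log10 contact distance for cis
PETs (distance 0 excluded — undefined on the log scale) and reports the
fraction of contacts in configurable distance bands. The default single
band edge at 10 Mb splits compartment-scale interactions (≥ 10 Mb) from
TAD/loop-scale interactions (< 10 Mb), the standard first-look summary
for detecting a global shift between compartment- and domain-level
organization.

## Compartment eigenvector (PC1)

Per sample and chromosome, the raw 100-kb matrix is distance-normalized:
expected(d) is the mean count over valid bin pairs at offset d, and
O/E[i,j] = M[i,j]/expected(|i−j|). PC1 is the eigenvector of the largest
eigenvalue of the Pearson correlation matrix of O/E columns (pairwise-
complete over valid bins), the convention of standard Hi-C compartment
callers. Eigen-decomposition is exact (`numpy.linalg.eigh`); with at
most a few thousand bins per chromosome there is no reason for power
iteration. Bins with zero coverage, all-missing or constant O/E columns
are masked and re-inserted as NaN; the eigenvector has unit norm over
valid bins.

PC1 is defined only up to sign. `orient_pc1` multiplies by −1 when the
Pearson correlation with a per-bin reference covariate (high in
compartment A) is negative, and flags |r| < 0.1 as ambiguous. Every
sample is oriented against the *same* reference — never against another
sample — so the result is order-independent. In synthetic mode the
reference is the condition-1 ground-truth A/B labels (+1/−1); for real
data a user covariate such as gene density plays this role.

## Two-pass Mahalanobis differential test

The core statistic. For a feature × sample matrix X (rows: 100-kb bins
with PC1 values, or TADs with enrichment scores; columns: samples),

    MD = diag((X − Xc) · C⁻¹ · (X − Xc)ᵀ)

with Xc the feature-wise centroid and C the unbiased (n−1) sample
covariance of the columns. This is the *squared* Mahalanobis distance
and is used as such: for approximately Gaussian columns the squared MD
of a p-vector is χ² with p degrees of freedom, so each feature gets a
one-sided upper-tail χ²(df = number of columns) p-value.

Pass 1 estimates Xc and C from all features and flags p < α (default
0.01) as outliers. Pass 2 re-estimates Xc and C excluding those
outliers and rescores *all* features against the cleaned estimates;
pass-2 p-values are the final ones. The two passes matter because the
interesting features (switched bins, changed TADs) inflate the pass-1
covariance and would otherwise mask themselves. No multiple-testing
correction is applied: the raw p < 0.01 cutoff is the method's
published operating point (α is configurable).

Numerical choices: a covariance whose rank is deficient at relative
tolerance 1e-10 falls back to the Moore–Penrose pseudo-inverse and the
result is flagged (`singular_covariance`); tiny negative MDs from
roundoff of the PSD quadratic form are clipped to 0; the test errors out
when fewer than p+2 features survive pass 1.

A structural property worth knowing: with n features, a single outlier's
pass-1 MD is bounded by (n−1)²/n, so pass 1 can only engage the χ² 0.01
tail when the matrix has dozens of rows or more. The test is meant for
hundreds-to-thousands of features; tiny matrices degenerate to a single
pass.

Significant compartment bins are classified by the signs of the
per-condition mean PC1: (+,−) → A→B, (−,+) → B→A, (+,+)/(−,−) →
stable-compartment shifts. Bins with PC1 exactly 0 in either condition
are indeterminate and excluded from counts. Replicates are summarized
into per-condition columns by the arithmetic mean (separate-column mode
is available through the FeatureMatrix interface).

## TAD strength

TAD intervals are inputs (TAD calling is out of scope). For one TAD,
ES = intra / inter where intra counts PETs with both ends inside the
half-open interval and inter counts PETs with exactly one end inside. An
end exactly at the TAD end coordinate is outside. inter = 0 is guarded
(denominator floored at 1, row flagged and dropped from the comparison
matrix). A PET spanning two different TADs counts as "inter" for each.
The ES matrix (TADs × samples) feeds the same two-pass MD test, on raw
ES values (a log2 option exists but is off by default, matching the
statistic's published form); significant TADs are labelled
condition1-/condition2-specific by which condition has the higher mean
ES.

## HiChIP viewpoint enrichment

Each viewpoint (peak summit/midpoint) maps to one 1-kb bin v. With W the
set of bins within ±100 kb of v (≤ 201 bins, truncated and flagged at
chromosome ends), anchored(b) = Σ_{b'∈W} M[b,b'] and

    ES = anchored(v) / mean_{b∈W} anchored(b),

i.e. the viewpoint's total contact mass within the window relative to
the window-average anchored mass, so ES ≈ 1 means no enrichment. The
window mean includes the viewpoint bin itself (a ≤ 1/201 effect). This
is the simplest definition consistent with "±100-kb background"; the
function is versioned so a median-background variant can be swapped in.
A window mean of 0 leaves the score undefined (NaN, flagged), and such
records are dropped from category aggregation with a warning.

For display only, window submatrices are compressed with two rounds of
log10 with a +1 pseudo-count per round, T(x) = log10(1 + log10(1 + x)):
monotone, maps 0 to 0, and tames the heavy-tailed counts; it never feeds
statistics.

## Virtual 4C

The bait must align to exactly one 5-kb bin (off-grid or multi-bin baits
are rejected with a re-alignment message rather than summed). The track
is the bait row of the VC_SQRT-normalized matrix; masked (zero-coverage)
bins carry NaN, and a zero-coverage bait yields an all-masked flagged
track. VC_SQRT divides each entry by the square root of the product of
its raw row and column coverage sums, M'[i,j] = M[i,j]/√(c_i c_j) — the
vanilla-coverage square-root normalization — with no global rescaling
constant, since every downstream use is ratio- or shape-based (the
normalization is exactly invariant under global scaling of the matrix).

## Poisson differential peaks

Peak read counts (peaks are inputs; calling is out of scope) are
depth-normalized to a nominal 30 million reads per sample and averaged
over replicates per condition. For each peak, with hi/lo the
larger/smaller normalized mean: λ = max(lo, 1), p = P(K ≥ round(hi) | λ)
(one-sided Poisson upper tail), FC = (hi+1)/(lo+1). A peak is
condition-selective iff p < 1e-5 AND FC ≥ 2, directed toward the higher
condition; ties and double zeros are shared. The λ floor and +1
pseudo-counts guard zero rates and zero divisions; rounding hi to the
nearest integer keeps the tail probability on the discrete lattice (a
continuous regularized-gamma variant is a config switch). The test is
symmetric under condition swap up to direction, and p and FC are
monotone in hi at fixed lo.

Peaks are annotated as promoters when the midpoint lies within 2 kb
(inclusive at the boundary) of the nearest transcription start site,
else enhancers. Signal quantification assigns read midpoints to
non-overlapping intervals and reports counts-per-million of total reads.

## Synthetic data generator

One PET is drawn by sampling a distance d from the truncated power law
p(d) ∝ d^−α on [1 kb, chrom_length), placing the left end uniformly,
and accepting with probability proportional to

    w = same_compartment_weight^[same A/B label]
      × tad_enrichment^[both ends in one TAD]
      × loop_strength^[ends within width of a loop anchor pair]

via rejection against the global weight bound. The sampler is a pure
function of (config, condition, replicate): child generators come from
`SeedSequence([base_seed, condition, replicate])` and the proposal batch
size is fixed, so output is byte-reproducible. An acceptance rate below
1e-3 aborts with a diagnostic (the bound scales with the maximum loop
strength, which is what makes pathological configs slow).

The default benchmark scenario is a single 60-Mb chromosome — the
statistics are per-chromosome composable, so one chromosome suffices and
keeps runs desk-sized — at 2 conditions × 2 replicates × 1e6 PETs:

* **Compartments:** 30 alternating A/B blocks (2.8 Mb / 0.4 Mb / 2.8 Mb
  per 6-Mb group); the ten 0.4-Mb mid-group blocks flip label in
  condition 2 (40 of 600 100-kb bins, 6.7%). Flipped regions are
  deliberately sub-Mb: compartment switching is an outlier phenomenon,
  affecting a small minority of bins genome-wide, and the Mahalanobis
  covariance estimate presumes exactly that. If flips covered ~half the
  chromosome the young/old PC1 correlation would collapse toward zero
  and no bin could reach the χ² tail — a regime the statistic is not
  designed for and real data does not present. Same-compartment weight
  2.0 produces an unmistakable checkerboard at 1e6 PETs.
* **TADs:** 100 non-overlapping TADs (300/400/500/600 kb cycling,
  150-kb gaps, enrichment 2.0); every tenth starting at index 5 is
  scaled ×0.5 in condition 2.
* **Loops:** 50 loops, one per even-indexed TAD, anchor separation
  50 kb — inside the ±100-kb viewpoint background, since a loop longer
  than the background window cannot contribute to its own viewpoint
  score — strength 40 at 2-kb anchor width; every fifth starting at
  index 2 is scaled ×0.25 in condition 2. Anchor-1 positions double as
  the 50 viewpoints. Strength 40 corresponds to the strong focal
  enrichment HiChIP shows at 1-kb anchor resolution; per-viewpoint ES
  differences at this depth are ~0.3 with per-viewpoint noise of
  similar size, which is why the loop comparison is a paired rank test
  over viewpoints rather than a per-viewpoint call.
* **Decay:** α = 1, the canonical contact-decay slope in the sub-10-Mb
  regime.
* **Peaks:** 10,000 peaks, log-normal base rates (σ = 0.8) scaled so
  peak reads are 30% of a 30M-read sample, 10% differential at fold
  change 4 (half up, half down), independent Poisson replicates.

What the generator does *not* emulate: trans contacts, nucleotide
sequence or read-level artifacts (no FASTQ), restriction-fragment
structure, copy-number or mappability bias, nested/hierarchical TADs,
compartment strength gradients, or correlated replicate noise
(replicates are independent draws). Passing recovery tests therefore
demonstrates that the statistics are implemented correctly and behave as
designed under their own model assumptions — not that they are robust to
every artifact of real libraries.

## Problem sizes and validation

The test suite and the acceptance script validate, per run: brute-force
agreement of the vectorized MD (1000 × 2 and 1000 × 4), χ² calibration at
the 1%/5% quantiles, null false-positive fraction (5 × 10⁴ correlated-
normal rows; empirically ~0.012 at α = 0.01 — the two-pass re-centering
is mildly anti-conservative, inside the expected [0.002, 0.03] band),
compartment-flip recovery and precision on the 600-bin scenario at
2 × 2 × 1e6 PETs, TAD recovery over three scenario seeds, the worked ES
examples (8/4 → 2.0; uniform window → 1.0), Poisson-test exactness
against direct pmf summation plus recovery on 10⁴ simulated peaks,
virtual-4C track semantics and a planted 200-kb loop (≥ 2× flank
median), PC1 checkerboard correctness and ≥ 95% ground-truth sign
agreement, and byte-identical summary JSON across repeated `run_all`
invocations (determinism is depth-independent; the repeated run uses
1.5e5 PETs per replicate to keep the double execution brief).

## Known limitations

* The MD test assumes approximately Gaussian feature values per column;
  strongly skewed ES distributions would motivate the log2 option.
* χ² calibration of the two-pass procedure is approximate (~1.2% at
  nominal 1% under the null here); the published cutoff is used as an
  operating point, not an exact error guarantee.
* The viewpoint ES definition (window-mean background, viewpoint bin
  included) is one reasonable reading of a background-normalized
  enrichment; alternatives (median background, bin excluded) change
  scores by small amounts and are easy to swap.
* Rejection sampling cost grows linearly with the maximum enrichment
  weight; loop strengths far beyond ~100 call for a mixture-proposal
  sampler rather than a larger global bound.
* Single chromosome, cis only, point-coordinate PETs (real pipelines
  use fragment midpoints).
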