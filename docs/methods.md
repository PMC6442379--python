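# Methods

This note documents the models implemented in `hicarch`, their parameters
and defaults, the synthetic-data generator used for validation, and the
design choices made where the underlying methods are conventionally
under-specified.

## Coordinate system and fragment binning

All coordinates are 0-based, half-open. Restriction digestion reports the
first base of each exact motif occurrence (overlaps included); fragment
boundaries sit at cut positions (blunt model — no offset for enzyme
overhangs). Bins derive from fragments by a single left-to-right merge
pass (a cut closer than `min_width` = 150 bp to the previously kept
boundary is dropped; a terminal stub shorter than `min_width` merges into
its neighbour) followed by splitting any interval wider than
`max_width` = 1 kb into `ceil(w/max_width)` near-equal sub-bins, the first
sub-bins taking the remainder. The merge/split order and the blunt-cut
convention are choices; alternative conventions shift bin counts by a few
per cent on real genomes, which is why external bin-count figures should be
treated as approximate cross-checks rather than exact targets.

## Contact matrices

Counts are symmetric and stored upper-triangular in sparse CSR over the
global bin index; analysis operations densify one chromosome at a time
(the package targets chromosome-scale matrices of up to a few thousand
bins per chromosome at analysis resolution). Distances between fragment
bins are midpoint distances. Down-sampling to a target total draws a
multivariate hypergeometric sample over cells, i.e. an exchangeable subset
of the original contacts: the target is met exactly and a fixed seed is
reproducible. The log2 ratio map between libraries normalizes each by its
total and uses a pseudocount defaulting to one contact in the smaller
library. Expected counts for O/E are per-chromosome per-diagonal means
over unmasked cells; enriched contacts are cells whose log O/E is ≥ z
(default 2.0, a choice — the threshold is exposed) standard deviations
above their diagonal's mean, with diagonals of fewer than 3 defined cells
skipped.

## Correction

Coverage scores are `(log2 cov − median log2 cov) / MAD(log2 cov)` over
nonzero-coverage bins. The masking thresholds (−1.4, 5) follow the
convention for restriction-fragment resolution; (−2.4, 5) and (−3.0, 5)
are typical at 100-kb bins. These thresholds target the pathological
coverage tails of real libraries. Synthetic matrices have no such tails —
their coverage spread is the planted log-normal bias the balancer is
supposed to remove — so all recovery analyses mask zero-coverage bins
only; applying −1.4 MAD there would discard ~18% of healthy bins.

ICE is symmetric iterative proportional fitting: the bias of each unmasked
bin is repeatedly multiplied by the square root of its relative row sum
until the coefficient of variation of row sums falls below `tol` = 1e−5
(`max_iter` = 1000; non-convergence returns a flagged result). KR is the
inner–outer Newton conjugate-gradient iteration of Knight and Ruiz;
reducible matrices are balanced per connected component with a warning.
Both report bias on the same convention (corrected = raw / (bias_i bias_j),
unit geometric mean over unmasked bins), so the two agree up to a global
scalar on positive matrices.

## TAD-separation score and border calling

Each intra-chromosomal diagonal is z-normalized over unmasked cells (mean
0, SD 1), which makes the score depth- and scale-invariant. At a bin edge
k, the diamond of depth w covers rows [k−w, k) × columns [k, k+w); the
per-window score is the mean z inside the diamond and the aggregate score
is the mean over window sizes (default {10, 20, 30} kb, converted to bins
by the median bin width). Evaluation points are the bin edges nearest each
multiple of `step` (default 2 kb); a point is defined only when every
window fits in the chromosome and no diamond is more than half masked.

Border candidates are aggregate-score minima over a neighbourhood of
±max(`min_boundary_distance`, w_max · bin width): a dip narrower than the
measuring diamond cannot be resolved as a separate border, so jagged
secondary minima on a genuine boundary's valley slope are not candidates.
Delta is the mean score over the ±`min_boundary_distance` (5 kb) flank
minus the score at the minimum; candidates with delta ≥ 0.04 receive a
one-sided Mann–Whitney p-value comparing the boundary diamond's z-values
against pooled intra-domain flank diamonds placed a full window away on
each side (disjoint from the boundary diamond — overlapping flanks have no
power). Benjamini–Hochberg q ≤ 0.01 keeps a border; remaining borders are
pruned to the 5-kb minimum spacing (larger delta wins, ties leftmost), and
domains narrower than 5 kb are dissolved by dropping their weaker bounding
border. Strong borders have delta ≥ 0.08 (inclusive).

Cross-cell classification uses nearest-counterpart distance per
chromosome: 0 → conserved (an identical restriction-site coordinate),
< 2 kb → fuzzy, ≥ 2 kb → cell-type-specific. Strict coordinate equality
implements "conserved"; fuzzy absorbs near misses.

## Divergent transcription

For a border at p, `R+` sums plus-strand signal over [p+500, p+1000) and
`R−` sums minus-strand signal over the mirrored [p−1000, p−500); the
directionality score is `D = log10((R+ + ψ)/(R− + ψ))` with ψ = 1 signal
unit. A border is bidirectional when |D| < 0.47: the cutoff is log10(3)
= 0.4771… truncated to two decimals, i.e. "less than three-fold more
transcription on one strand". The absolute value realizes the symmetric
reading of that criterion; a signed variant is available via
`classify_bidirectional(..., signed=True)`. Mann–Whitney U (peak levels
within ±1 kb of borders) and two-sample KS (score distributions) use exact
enumeration over all label assignments for combined n ≤ 20 and the
standard tie/continuity-corrected normal or asymptotic approximations
above that.

## Loops

On a KR-balanced fixed-resolution matrix (default 2 kb), every pixel at
anchor offset ≥ `peak_half_width`+1 bins is tested against the mean of
balanced counts in the donut annulus (Chebyshev radius in (5, 10] bins,
excluding the row/column cross), rescaled to raw-count space through the
bias vector and used as the rate of a Poisson upper-tail test on the raw
count. Benjamini–Hochberg controls the FDR at 0.05 across tested pixels;
significant pixels are single-linkage clustered within 20 kb (Chebyshev)
and each cluster is represented by its most enriched pixel. This is a
deliberately simplified donut caller: the published HiCCUPS scheme adds
lambda-chunking, three further local filters and post-hoc enrichment
thresholds, which changes absolute loop counts; the simplification is the
package's design choice and its false-discovery behaviour is validated on
null simulations instead.

Loop placement relative to TADs: a loop is `at_border` if either anchor is
within 1 bin of a border, `within_tad` if both anchors fall in the same
domain, else `between_tads`.

## Compartments

Per chromosome, the corrected matrix is O/E-transformed, converted to a
Pearson correlation matrix over unmasked bins, and the eigenvector of the
largest eigenvalue extracted. Because the eigenvector sign is arbitrary it
is oriented by its correlation with GC content (GC-richer = A); positive
entries are A, negative B, masked or GC-less bins N, and chromosomes with
fewer than 10 usable bins are entirely N. Switch summaries report
transition fractions over bins classified A/B in both tracks.

## Statistics for annotation overlap

Fisher's two-sided exact test sums hypergeometric point probabilities not
exceeding the observed one (relative tie tolerance 1e−7); a zero margin
returns p = 1 with a warning. The randomization test permutes group labels
(hypergeometric redistribution of successes), uses |p̂₁ − p̂₂| as the
statistic and the add-one estimator (1 + #{perm ≥ obs})/(n_perm + 1), and
reports a Monte-Carlo standard error. Border–interval overlap uses a ±1 kb
window around the border coordinate by default (matching the profile
window; the overlap window itself is a convention) with half-open
semantics; a zero window degrades to a point query.

## Synthetic-data generator

The generator is first-class, deterministic under a seed, and emits truth
records sufficient to score every stage without re-simulation. Expected
counts for bin pair (i, j) at distance d bins are

    mu_ij = Z · b_i b_j · (d·w + s0)^(−α) · τ^[same TAD]
            · (1 + c·e_i e_j) · λ^[loop pixel]

with Poisson sampling and Z set so the expected upper-triangle total is N.
Standard conditions: 500 bins × 2 kb (a 1-Mb chromosome), N = 1e6, decay
exponent α = 1 with offset s0 = 1 kb, within-TAD enrichment τ = 2.5,
checkerboard strength c = 0.3, loop enrichment λ = 6, log-normal bias with
σ = 0.25. Cell A and cell B share 4 conserved borders and carry 3 specific
borders each (8 domains per cell); fuzzy borders (offsets of {bin width …
1999} bp snapped to bin edges) require bin widths below 2 kb and are
exercised at 500-bp bins. Transcription tracks put 500-bp rectangles of
rate 20/bp on the plus strand downstream and the minus strand upstream of
each divergent border (default: 75% of borders, strand ratio 1:1) over
Poisson background of 0.02/bp; enhancers (400 bp) and GRBs (5 kb) are
placed at borders with class-dependent probabilities (defaults 0.6 at
A-specific vs 0.2 at conserved borders for cell-A enhancers).

Two structural constraints keep the planted truth complete:
compartment-block transitions sit on conserved borders (a checkerboard
transition is itself an insulation boundary, and in real genomes
compartment switches align with domain boundaries — free placement would
plant borders the truth does not record), and loop pixels sit inside
shared domains at anchor offsets of 40–120 kb, where a 1-Mb, 1e6-contact
chromosome carries enough counts for focal detection (a 6-fold enrichment
on an expected background below one count is statistically invisible at
any FDR). Cell B's compartment switching flips whole conserved-bounded
blocks until roughly the requested bin fraction (10%) has changed sign.

What the generator does not emulate: fragment-length heterogeneity
(fixed-width bins in the standard preset), dangling-end/religation
artefacts, trans contacts, overdispersion beyond Poisson, distance-
dependent loop footprints wider than one pixel, and replicate-level
variability. Passing recovery tests therefore demonstrates correctness of
the algorithms under the stated generative model, not performance on real
libraries with those pathologies.

## Problem sizes and determinism

Recovery analyses aggregate 10 independent seeds of the standard
simulation (70 planted borders, 80 planted loops, 5000 bins scored for
compartments and bias). Exact-test cross-checks enumerate all 135,751
2×2 tables with total ≤ 40 and all label assignments for the rank tests at
combined n ≤ 13. Every stochastic step takes an explicit seed; the
pipeline derives per-stage seeds from the run seed, and re-running with
the same configuration reproduces summary outputs byte-for-byte.

## Known limitations

- The donut caller tests single pixels; broad (multi-pixel) loops are
  reported as their most enriched pixel after merging.
- Expected models are intra-chromosomal only; no inter-chromosomal
  normalization or trans-based compartment calling.
- The TAD caller reports bin-edge coordinates; sub-bin localization is out
  of scope.
- Fisher/permutation agreement is expected only for moderate tables; for
  very unbalanced margins the permutation null is coarse and the add-one
  estimator floors p at 1/(n_perm+1).
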