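# Methods

This note documents the models, conventions, numerical choices and known
limitations of the toolkit, and what the synthetic ground-truth data do
and do not establish about behaviour on real data.

## Coordinates, containers and normalization

All genomic coordinates are 0-based, half-open; 1-based inputs must be
converted at the reader boundary. Contact matrices are dense, symmetric
(tolerance 1e-9), nonnegative, one chromosome at a time; the dense
representation bounds practical inputs to roughly 25,000 bins per
chromosome, which is a documented contract rather than a hidden failure
mode. The matrix total is the sum over the full symmetric matrix with the
diagonal counted once; `normalize_to_total` (default 100 million
contacts) scales to this convention, per chromosome — callers comparing
conditions genome-wide should normalize each chromosome with a common
target.

Observed/expected divides each diagonal by its mean over covered bin
pairs (covered = nonzero marginal). Diagonals with zero mean are set to 0
with a warning, not NaN, so downstream correlation matrices stay defined.

Relative contact probability (RCP) uses logarithmically spaced distance
bins, 10 per decade by default, reported at the geometric midpoint. The
curve is the pair-count-normalized mean contact frequency per distance
bin, renormalized to sum to 1; this makes the curve invariant to
sequencing depth and gives a matrix with contact decay s^γ a log-log
slope of γ. Empty distance bins report probability 0 and are flagged.
With replicate matrices the per-replicate curves are averaged and the
standard error of the mean is reported. No monotonicity is imposed.

## In-silico digestion

Cuts are placed at the start of every motif occurrence (5′ convention,
matching DpnII chemistry at GATC); overlapping occurrences each cut, and
zero-length fragments from adjacent or terminal motifs are dropped, so
the fragments tile the sequence. A fragment is *blind* when no occurrence
of the second enzyme's motif (Csp6I, GTAC, for 4C) is fully contained in
it; blind fragments carry no circularizable signal and are filtered
before peak calling. Mappability is not computed internally: non-unique
regions enter as a user-supplied mask.

For DamID, GATC fragments overlapping any unmappable block larger than
5 kb are dropped (any overlap with such a block disqualifies the
fragment), then remaining fragments are concatenated greedily
left-to-right until the cumulative constituent length reaches 50 kb;
every extended fragment therefore starts and ends on a GATC boundary and
only the terminal fragment of a chromosome may be shorter. Dropped
fragments do not contribute to the window length but do not split runs.

## 4C peak calling

The model assumes background contact frequency is non-increasing in
distance from the viewpoint, fitted independently per side and per
replicate by exact isotonic least squares (pool-adjacent-violators, via
scikit-learn). Distance is absolute bp from the viewpoint center.
Fragments within an exclusion zone around the viewpoint (default 10 kb)
are removed before fitting and testing — the over-amplified
viewpoint-proximal zone otherwise dominates the fit. A side with fewer
than two fragments keeps its observed values as the degenerate fit, with
a warning.

Enrichment per fragment uses both R = obs/max(b, ε) and Δ = obs − b, with
ε = 1 read guarding the ratio on sparse counts. R and Δ are each ranked
high-to-low with average ranks on ties; the average of the two ranks is
ranked again (ties averaged) to give one rank per fragment per replicate;
replicate ranks multiply into the rank product r. The p-value is the
Gamma(k, 1) upper tail at −ln(r/(n+1)^k). This approximation is exact
when ranks are continuous uniform on (0, n+1); for discrete ranks it is
conservative at very small r (the true discrete tail is smaller than the
Gamma tail by an O(1/n) margin), which makes the caller err toward fewer
calls — the calibration test bounds the null fraction below α at 1.5α.
Exact enumeration of the discrete rank-product distribution exists but is
prohibitive at realistic fragment counts and is not implemented.

Peak segmentation takes fragments with P < α (default 0.01), allows
`merge_gap` (default 1) non-significant fragments inside a peak, and
requires `min_fragments` (default 3) significant fragments per peak.
The minimum-run requirement is essential for specificity: p-values are
approximately uniform under the null, so isolated sub-α fragments are
expected in any profile (about n·α of them), while a genuine 4C
interaction spans several restriction fragments; requiring three
significant fragments drops the expected false-peak count to about
n·α³ per profile. Monotone-fit inflation near strong peaks (the
non-increasing fit pools peak fragments with their neighbours, raising
the local background) reduces the nominal R at peaks but leaves the
rank-based inference effective, as the recovery tests show. The
background fit is unweighted; windowed or weighted variants of monotone
4C backgrounds are out of scope.

## Loops

Loop length is the anchor-midpoint separation — midpoints are robust to
the calling resolution. Flanking (near-duplicate) loop calls merge when
both corresponding anchor midpoints lie within `tolerance_bins` ×
resolution (default 1 bin), with transitive closure and union anchors;
the merge operates on anchor intervals, not on 2D pixel space. CTCF
orientation is assigned only when both anchors overlap exactly one
distinct motif strand: 5′ forward with 3′ reverse is convergent (motifs
pointing toward each other), equal strands tandem, the reverse pair
divergent, everything else unassigned. Extended loops pair the 5′ anchor
of loop A with the 3′ anchor of any loop B whose 3′ anchor lies beyond
A's and whose 5′ anchor midpoint is at least 30 kb from A's (strictly
less than 30 kb excludes, i.e. effectively "not the same 5′ anchor");
duplicates and existing primary loops are removed. Densities of loop
lengths use a Gaussian kernel (scipy).

## Pile-ups

APA windows are (2·flank/bin + 1)² submatrices centred on the coordinate
bins; coordinates whose windows cross the matrix edge are skipped and
logged, never zero-padded, because padding biases the mean. ATA extends
each TAD by 50% of its size per border and rescales by bilinear
interpolation on bin-center coordinates (so a window already at the
output size passes through unchanged); nearest-neighbour resizing is
available for exact small-case checks. Differential aggregates default to
log2 ratio with a pseudocount of 1 contact and require inputs normalized
to a common total; a signed difference mode is also provided. The loop
score divides the center pixel by the mean of pixels at Chebyshev
distance greater than a quarter of the window size from the center.
TAD-size filtering for differential ATA (e.g. restricting to 500 kb–1 Mb
domains) is the caller's responsibility via the TAD list.

## TAD scores and directionality index

TAD intervals map to bin spans by bin centers (a bin belongs to the TAD
whose half-open interval contains its center). intraTAD sums the upper
triangle of the diagonal block including the diagonal; interTAD sums the
full rectangular block and requires disjoint spans. Neighbor ratios visit
each ordered pair of kept TADs (≥ 200 kb) within 10 flanking TADs once,
computing log2 of the interTAD scores of the two (equally normalized)
conditions; zero-score pairs are skipped and flagged. Stratification of
TADs by expression or any other label is left to the caller via the TAD
list contents.

DI uses 2 Mb windows by default on 10 kb matrices. Bins whose full window
does not fit in the chromosome, and bins with A + B = 0, are masked NaN.
Aligned DI profiles stack ±100 kb (default) windows around every 5′ TAD
border and average NaN-aware; differential profiles subtract a named
reference condition.

## Compartments, switches and LADs

Compartment scoring masks zero-coverage bins, computes observed/expected,
takes the Pearson correlation matrix over covered bins and its leading
eigenvector (largest eigenvalue). The eigenvector sign is arbitrary, so a
reference track (e.g. gene density, or the wild-type scores when
comparing conditions) orients it: the sign is flipped until the
correlation with the reference is positive. A constant (degenerate)
correlation matrix is an error. Scoring is per chromosome.

Switch detection computes the threshold (P85 − P15)/2 from the wild-type
scores, flags bins with a sign flip and an absolute difference above the
threshold, merges adjacent same-direction bins into intervals and reports
megabase totals per direction. The detector works on single bins before
merging; pre-smoothing the tracks is left to the caller.

DamID log-ratios use a pseudocount of 1 read per channel; fragments with
zero coverage in both channels are masked. "Enriched" means log-ratio
above 0 by default. LAD construction seeds runs of enriched fragments and
merges adjacent runs whenever the total non-enriched base pairs inside
the candidate LAD stay strictly below 20% of its length. Merging is
best-first — among all admissible adjacent pairs, the one with the
smallest non-enriched fraction merges first, repeated to a fixpoint —
rather than a left-to-right sweep: the chain criterion depends only on
the merged span, so a directional sweep can resolve a three-run conflict
differently in the two scan directions, whereas best-first merging is
symmetric under coordinate reflection (up to exact ties, which jittered
fragment sizes make measure-zero in the tests).

## Synthetic data

Generators are statistical stand-ins, not polymer or loop-extrusion
simulations. Contact matrices: E[C_ij] = base·max(|i−j|,1)^γ times
multiplicative planted factors (TAD blocks, loop pixels, compartment
plaid 1 + κ·v_i·v_j with κ = 0.3 by default — strong enough for reliable
eigenvector recovery, weak enough to be nontrivial), with Poisson counts
mirrored across the diagonal (exactly symmetric integers); γ defaults to
−1, the canonical contact-decay slope. 4C profiles: strictly decreasing
background per side (shifted power law, 150 fragments per side at ~1 kb
spacing with jitter), planted peaks multiply the background over a 5 kb
width, and counts are negative binomial (Var = μ + 0.1·μ², the
overdispersion typical of 4C; dispersion 0 returns the exact mean).
DamID: two-level Gaussian tracks (+1 in planted LADs, −1 outside,
σ = 0.3) over ~50 kb fragments with jittered sizes. All generators are
bit-reproducible under a fixed seed and return the planted truth as a
JSON-serializable object.

What passing tests show — and do not. Recovery results (peak
sensitivity/specificity, LAD base-pair recovery, eigenvector correlation,
DI boundary detection) hold under the generators' assumptions: clean
monotone 4C backgrounds, homogeneous dispersion, uniform mappability,
sharp planted boundaries, no translocations or copy-number effects. Real
data violate all of these to varying degrees; the tests validate the
statistical machinery and its implementation, not field performance.

## Problem sizes and defaults in the shipped checks

The test suite and the acceptance script run matrices of 200–900 bins,
4C profiles of ~300 fragments × 3 replicates, 15–50 simulation seeds per
claim and a 10⁶-draw Monte-Carlo null — sizes chosen so every claim is
measured on hundreds of planted features while the whole suite completes
in seconds. The demo pipeline (600-bin 10 kb matrices, 300-bin 100 kb
compartment matrices, 200 planted loops, 200 DamID fragments) writes
TSV/JSON only, so fixed-seed runs are byte-reproducible.

## Known limitations

- No matrix balancing (ICE/KR) and no trans-chromosomal analysis; inputs
  are taken as provided.
- No loop or TAD calling from matrices; interval lists are inputs.
- Dense matrices bound chromosome size at working resolution.
- The Gamma rank-product p-value is approximate for discrete ranks
  (conservative at extreme significance); no exact enumeration and no
  built-in multiple-testing correction — α, the merge gap and the
  minimum peak size are exposed parameters.
- The compartment eigenvector needs an external reference for sign
  orientation, and compartment scoring assumes a single chromosome.
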