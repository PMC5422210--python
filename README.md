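# loopscape

Analytics for chromosome-conformation and nuclear-lamina data: a
multi-replicate 4C-seq peak caller built on monotonic-regression
backgrounds and rank-product inference, Hi-C pile-up analysis (APA/ATA),
TAD interaction scores and directionality index, A/B compartment scoring
with switch detection, and DamID LAD calling — all exercisable on
synthetic datasets with planted ground truth.

The package is aimed at computational genomicists who work with binned
intra-chromosomal contact matrices, 4C fragment-end coverage tables and
DamID GATC-fragment counts, and who need the bespoke statistics of
cohesin/CTCF chromatin-architecture studies without the upstream read
processing (mapping, matrix building and published loop/TAD callers are
out of scope; inputs start at matrices, coverage tracks and interval
lists).

## The statistics at the core

**4C peak calling.** The background contact frequency of a 4C viewpoint
decreases monotonically with genomic distance, independently upstream and
downstream. Per replicate the background *b* is the least-squares
non-increasing fit of coverage against distance (isotonic regression via
pool-adjacent-violators). Each fragment end is scored by the ratio
*R* = obs/*b* and the difference *Δ* = obs − *b*; *R* and *Δ* are ranked
high-to-low, the average of the two ranks is ranked again, and the
per-replicate ranks are combined across *k* replicates by their product
*r*. With *n* fragments, the p-value uses the Gamma approximation

    P = 1 − F_Γ(k,1)( −ln( r / (n+1)^k ) )

which reduces to P = r/(n+1) for k = 1. Fragments with P < α are merged
into peaks (a configurable number of non-significant fragments may be
bridged; peaks must contain a minimum number of significant fragments).

**Pile-ups.** APA averages fixed windows around 2D coordinates (with
10 kb bins and 100 kb flanks: a 21×21 submatrix); ATA extends each TAD by
50% of its size on both borders and rescales the window to 100×100 before
averaging. Loop scores divide the center pixel by the mean of the
surrounding region.

**TADs.** For TADs *A* (windows *a′..a″*) and *B* (*b′..b″*) on matrix
*C*: intraTAD(A) = Σ_{i=a′..a″} Σ_{j=i..a″} C_ij and
interTAD(A,B) = Σ_{i=a′..a″} Σ_{j=b′..b″} C_ij, with log2 inter-TAD
ratios computed against up to 10 flanking TADs (TADs < 200 kb excluded).
The directionality index per bin contrasts upstream (A) and downstream
(B) contact sums in 2 Mb windows: DI = sign(B−A)·[(A−E)²/E + (B−E)²/E],
E = (A+B)/2.

**Compartments and LADs.** The leading eigenvector of the Pearson
correlation matrix of the distance-normalized (observed/expected) contact
matrix scores A/B compartments; switches between conditions require a
sign flip plus an absolute difference above (P85 − P15)/2 of the
wild-type scores. DamID tracks are log2(Lamin-Dam/Dam-only) per
50 kb-extended GATC fragment; LADs are runs of enriched fragments,
bridgeable across non-enriched stretches totalling strictly less than 20%
of the resulting LAD length.

## Worked example

```bash
loopscape demo --seed 1 --out demo_out
```

simulates a wild-type and a "mutant" condition (1.5× longer loops,
stronger TAD corner peaks, steeper far-cis decay, compartment flips,
expanded LADs) and runs every analysis. `demo_out/summary.tsv` from this
run contains, among others:

```
median_loop_length_wt_bp        376480.5
median_loop_length_mut_bp       564721.5
median_loop_length_ratio        1.500002
ata_corner_differential_log2    0.262299
rcp_far_cis_wt                  0.020960
rcp_far_cis_mut                 0.012167
switch_AtoB_mb                  2.9
n_4c_peaks                      2.0
```

Reading: the mutant's median loop length is 1.5× the wild-type's (the
planted factor); the aggregate-TAD corner pixel gains log2 ≈ 0.26 in the
mutant (stronger corner loops); far-cis contact probability drops
(0.0210 → 0.0122); 2.9 Mb of compartment switches in the planted
direction are detected; both planted 4C peaks are recovered. Per-analysis
tables (peak statistics, DI alignment, inter-TAD ratios, RCP curves,
compartment switches) and the planted-truth JSON sidecars are written to
the same directory, and a fixed seed reproduces the report byte for byte.

The same analyses are available as subcommands on real data files
(`loopscape rcp|peakc|apa|ata|di|tadscore|loops|compartments|lads`, plus
`loopscape simulate` for standalone synthetic data); matrices travel as
triplet text, intervals as BED, loops as BEDPE, tracks as bedGraph.

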