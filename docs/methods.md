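# Methods

## Interval grid and feature tracks

All genome-wide statistics live on a fixed tiling: per chromosome,
`ceil(length / width)` half-open intervals of `width` bp (default 10,000;
the terminal interval is truncated, and its true length is used wherever a
length normalization occurs, as in RPKM). Coordinates are 0-based half-open
internally; RepeatMasker `.out` (1-based inclusive) is converted on read.

Annotated elements are assigned to exactly one interval by their midpoint
`(start + end) // 2` under half-open lookup. This avoids double counting of
boundary-spanning copies and matches copy-number ("number of elements")
semantics; for elements much shorter than the interval width the choice of
rule is immaterial. Annotations on chromosomes absent from the grid are
skipped with a warning and counted in the track's `meta["n_skipped"]`.

GC content is (G+C)/(A+C+G+T) per interval, case-insensitive; intervals with
no unambiguous base are missing (NaN), never zero. RPKM counts each
placement of each read once, as a point at its 5′ position (the rightmost
aligned base for reverse-strand placements).

Missing values propagate: downstream correlations drop incomplete pairs
per cell (pairwise, not listwise) and report the per-cell `n_used`.

## Spearman correlation and stratification

`spearman_rho` is the Pearson correlation of average fractional ranks (ties
share their mean rank), delegated to `scipy.stats.spearmanr`; the test suite
holds it against an independent explicit rank-then-Pearson oracle, exactly,
on exhaustive small tied-vector families. P-values use the asymptotic
t approximation, per cell, with no multiple-testing correction. Degenerate
cells (constant input, fewer than 3 complete pairs) yield missing values
with a machine-readable reason code rather than exceptions.

Stratification splits intervals by a count track: *rich* means count
strictly greater than a threshold (default > 10 copies per interval), *poor*
means exactly equal to a threshold (default 0). The two natural readings of
"poor" (zero copies vs ≤ 1 copy) conflict in common usage; the zero-copy
reading is adopted because it makes the strata disjoint and is the stronger
contrast.

## Metarepetitive-element read classification

The signature rule operates on the set of repeat classes overlapped by a
read's placements (any overlap ≥ 1 bp counts; no minimum-overlap rule is
imposed):

* empty set → `NONREPEAT`;
* two or more distinct classes → `DISCARD`;
* exactly one class, but some placement hits no repeat → `DISCARD` by
  default (the read's signature is not purely single-class); a
  `mixed_policy="count"` switch assigns the class instead;
* exactly one class over all placements → that class.

Class vocabulary is a configurable grouping map from annotation families
(e.g., RepeatMasker `SINE/Alu`) onto reported classes (Alu, LINEs,
satellites, LTR); families absent from the map are treated as non-repeat.
Fractions divide per-class counts by the total over the reported classes
only, so they sum to 1; enrichment across timepoints is the ratio of
fractions, which is invariant to library size (raw-count ratios are not).
No read de-duplication is performed. Overlap queries use an interval tree;
the suite checks the classifier against a brute-force per-placement oracle,
exactly, on 20,000 simulated reads.

## Nuclear masking and colocalization

Nucleus segmentation: 3D Gaussian smoothing (σ = 1 px), Otsu threshold
(the "automatic" method), fill holes, binary dilation (2 iterations), fill
holes again, drop components below `min_volume` (default 400 µm³, a lower
bound for an intact cultured-cell nucleus). The dilation is a recall step —
it guarantees that peripheral foci are not excluded by a tight mask — and
inflates the measured volume by a surface shell of roughly the voxel pitch
per iteration; volume-accuracy checks therefore run with dilation disabled.

Background removal: per-plane local mean filter, window (2r+1)² with
r = 10 px by default (~0.87 µm at the reference pixel size), subtracted and
clipped at zero. Diffuse background survives the window and is removed;
focal signal narrower than the window is retained.

Colocalization per z-plane, over in-mask voxels only:
Pearson's r, and the H coefficient defined as the normalized intensity
cross-product `H = mean(I₁·I₂) / (mean(I₁)·mean(I₂))`. This definition is
adopted because it satisfies every property required of the score:
independence gives E[H] = 1 for any spatial structure of either channel,
co-enrichment gives H > 1, mutual exclusion pushes H below 1 (0 for
disjoint supports), and H is invariant under positive rescaling of either
channel. Note that on *sparse focal* channels the per-plane null
distribution of H around 1 is heavy-tailed (one chance overlap of two foci
moves a single plane's H by multiples of 1); meaningful null checks
therefore average planes within a cell and test cohorts of cells. The
reported per-cell value is taken at the mid-nuclear plane, selected as the
plane with the strongest in-mask DNA signal (deterministic tie-break to the
lower index).

## S-phase and cell-cycle staging

The EdU pattern classifier computes, per nucleus: mean in-mask EdU, the
number and mean volume of EdU foci (re-using the focus segmentation with a
permissive k = 2 threshold), the fraction of EdU intensity within a 1-µm
peripheral shell (anisotropy-aware Euclidean distance to the mask border),
and an intensity-weighted normalized depth. Rules, in order: EdU mean below
threshold → non-S; few large foci (≤ 20 foci of mean volume ≥ 0.4 µm³) →
late; peripheral fraction ≥ 0.4 → mid; otherwise early. The thresholds are
calibrated once per imaging condition (the defaults fit the generator's
reference condition) and are exposed in `SPhaseConfig`.

EdU-negative cells are split into G1 and G2 by 2-means clustering on
standardized (nuclear volume, integrated DNA intensity); the cluster with
lower mean DNA content is G1. A single EdU-negative cell is assigned G1
with a warning.

## Focus segmentation and repair kinetics

Foci are segmented inside (a 2-iteration dilation of) the nucleus:
threshold = in-nucleus mean + k·SD (k = 3 by default, calibrated once per
condition — low-SNR conditions need a lower k because the foci themselves
inflate the in-nucleus SD); a 3³ median filter applied to the intensity
image before thresholding removes single-voxel noise without eroding real
objects; touching objects are separated by a watershed whose seeds are
local intensity maxima at least 1 µm apart in *physical* (ellipsoidal
footprint) distance — intensity maxima rather than distance-transform
maxima, because equal-size merged foci produce a flat distance ridge with
no separable maxima; objects below 0.3 µm³ or not intersecting the dilated
nucleus are dropped. An empty result is valid (unirradiated cells).

The kinetics readout per cell is `fraction_in_regions`: summed probe
intensity inside the segmented focal regions divided by total in-nucleus
probe intensity (bounded in [0, 1]; the same operation serves the
reciprocal measurement of γH2AX inside segmented satellite regions).
Segmentation recovers the bright core of each focus, not its full planted
support, so the raw fraction carries a multiplicative core-vs-support bias;
normalizing each cell by the median raw fraction of the 0.5-h timepoint —
exactly the fold-change normalization used for the reported kinetics —
cancels it, which the end-to-end decay-recovery test exercises. Summary
statistics per timepoint are median, quartiles (linear-interpolation
quantiles), and whiskers at 3× the interquartile distance beyond the
quartiles. Unirradiated (0-h) images are excluded from kinetics.

## Synthetic data: what it emulates, and what it does not

*Tracks.* A Gaussian copula plants an exact target Spearman structure:
latent MVN with Pearson ρ_latent = 2·sin(π·ρ_S/6), margins transformed
monotonically (normal, lognormal for RPKM-like coverage, Poisson for copy
counts). For continuous margins the planted ρ_S is exact up to sampling
error; Poisson discretization introduces ties and a small attenuation,
visible in the recovery tolerances.

*Reads.* A 1-Mb toy genome interleaves 1-kb annotation blocks of four
classes separated by 500-bp unannotated gaps (wider than a read), so every
read's true outcome is unambiguous by construction: unique reads and
within-class multimaps carry their class, cross-class multimaps are true
`DISCARD`, gap reads are true `NONREPEAT`. Default class proportions
(0.47/0.24/0.15/0.14) mirror an early-damage-response composition over
Alu/LINE/satellite/LTR; multimap rate 0.2, of which a quarter cross-class.
Real repeat genomics is messier: nested and overlapping annotations,
mappability structure correlated with age of the repeat family, sequencing
error. Passing tests show the *accounting rule* is implemented exactly, not
that the rule is unbiased on real genomes.

*Images.* Nuclei are ellipsoids (default semi-axes 4 × 5 × 6 µm ≈ 503 µm³)
with smooth DNA texture; EdU patterns follow the substage phenotypes (early:
40 interior foci; mid: 40 foci in a ≤ 0.8 µm peripheral shell; late: 6 large
interior foci); damage foci are Gaussian blobs (σ = 0.5 µm, FWHM ≈ 1.2 µm,
typical of 2-Gy γH2AX foci, and comfortably above the 0.3-µm³ object
filter) planted ≥ 1.5 µm apart; all channels get Poisson noise over a
constant offset (default 2 counts). `focus_snr` is the Poisson detection
SNR at the peak, A/√(A + background). The FISH channel is either a
colocalization mixture α·reference + (1−α)·independent, where the
independent pattern is uniform over the whole nucleus so that α = 0 is a
true H-null, or (repair mode) a channel with a planted fraction of its
total intensity inside the damage foci. Not emulated: PSF/optics,
deconvolution artifacts, chromatic shift, nucleoli as distinct structures,
autofluorescence. Passing tests validate the measurement pipeline against
planted geometry, not microscope physics.

*Reproducibility.* One seed drives everything; per-cell sub-seeds are
spawned deterministically (`numpy` SeedSequence), and identical spec + seed
gives bit-identical outputs.

## Problem sizes and numerical choices

Cohort-scale image analyses (staging cohorts, kinetics timecourses,
focus-count sweeps) run at 0.25 µm isotropic voxels (~10⁵ voxels per
nucleus), which preserves every geometric feature the measurements depend
on; single-image examples use the reference acquisition geometry
(0.0866 × 0.0866 × 0.125 µm). Correlation recovery uses 10,000 intervals;
read classification 20,000 reads; kinetics 20–30 cells per timepoint.
Quantiles use linear interpolation throughout. Label assignment in masks
and foci is deterministic (raster order); watershed tie-breaks follow the
deterministic scikit-image implementation. Degenerate inputs (constant
vectors, empty strata, zero nuclear signal, missing baseline timepoint)
return flagged missing values or raise, as documented per function.

## Known limitations

The H coefficient lacks a universally agreed closed form in the literature
it comes from; the definition here is chosen for its null/enrichment
properties and scale invariance. The S-phase rules are linear thresholds on
three features and will need recalibration for cell types whose late-S
factories are smaller than ~0.4 µm³. The metarepeat denominator covers the
configured classes only; reads of unconfigured repeat families count as
non-repetitive. Real ChIP-seq fragment-length effects (reads extending past
annotation boundaries) are not modeled — placements are used as aligned.
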