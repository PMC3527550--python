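# Methods

This note documents the models, defaults and design decisions behind
each stage, what the synthetic generators do and do not emulate, and the
known limitations.

## Imaging chain

**Background subtraction.** "Rolling ball" is implemented as grayscale
morphological opening with a disk footprint (default radius 25 px); the
result is `clip(image − opening, 0)`. On a flat image this is exactly
zero and it is idempotent; structures wider than the disk are treated as
background. The radius is an exposed parameter because the appropriate
scale depends on magnification and punctum size.

**Segmentation.** The intensity threshold is chosen from the image's
gradient structure: candidate thresholds (intensity quantiles) are scored
by the mean Sobel gradient magnitude along the boundary of the resulting
mask, and the maximiser is used, with Otsu as fallback when no candidate
yields a usable boundary. Holes are filled, objects under `min_area`
(default 30 px²) are dropped, and touching objects are optionally split
by a distance-transform watershed. Watershed seeding is deliberately
conservative — peaks of the smoothed distance map at a minimum mutual
distance of 14 px, with a guaranteed single seed per connected
component — so isolated convex nuclei are never fragmented. Labels are
renumbered consecutively from 1; background is 0; coordinates are
(row, col), 0-based.

**Cell regions.** The cell body is approximated by dilating each nucleus
label by a fixed radius (default 10 px); contested pixels go to the
nearest nucleus. This is a deliberate simplification — no
cytoplasm-channel watershed — because a fixed-radius annulus is where the
generator places ligand puncta and where real juxtanuclear endosomal
signal concentrates.

**Quantification.** Per cell, the integrated background-subtracted
ligand intensity over its region; a marker channel (rescue-construct
expression) is integrated without background subtraction since it
reports expression level rather than puncta. The well readout is the
median over all cells pooled from all of the well's images; an empty
well yields a flagged missing value and is excluded downstream.

## Screen statistics

Within one experimental replicate, scores are
`(median_uptake − median(NC)) / SD(NC)` with the sample SD over the
negative-control *well* values of that experiment (not over cells).
This makes the NC score median exactly 0 and SD exactly 1, and makes
scores invariant to any positive rescaling of raw intensities.
Replicates are normalized separately and pooled; the across-replicate
mean is what is thresholded (the alternative — thresholding per
replicate — is not used, a recorded choice).

Thresholds: half the positive-control score for LDL and EGF; transferrin
uses a fixed default of 2 because receptor recycling leaves
plasma-membrane signal that makes the positive control an unreliable
scale. The boundary |mean| = threshold counts as a hit (thresholds are
printed as inclusive cut-offs). The t-test is a two-sided one-sample
test against 0; with one replicate, p is reported unavailable; with zero
replicate variance, p is 0 (mean ≠ 0) or 1, flagged degenerate. A
condition below threshold whose p ≤ 0.01 is still called, with
`subthreshold_significant` set — never silently.

Rescue analysis bins cells by marker intensity (quartiles by default —
the published analysis does not define bin edges) and reports per-bin
mean uptake, the monotone trend (concentration dependence), and the
rescue index = top-bin mean / reference-population mean.

With the default layout (8 negative-control wells per experiment), the
sample-SD estimate in the denominator inflates |score| by roughly 10%
relative to the planted effect; with many control wells the score
converges on the planted effect (the acceptance script reports both
regimes).

## Nuclei classification

Fixed 14-feature vector per nucleus: area, perimeter, eccentricity,
solidity, extent; mean, SD and 10/50/90% quantiles of normalized
intensity; integrated intensity; number of connected fragments of the
label; number of components above the 60% intensity quantile; mean
Sobel gradient inside the object. Intensity features are computed after
grey normalization (background median → 0, nuclei-pixel median → 1), so
they are invariant to illumination scaling. The feature list is a
documented stand-in validated against synthetic ground truth, not a
reproduction of any particular published feature set.

Classifier: RBF-kernel SVM (C = 1, gamma = 'scale') behind a
standardiser, with inverse-class-frequency weights
(`class_weight='balanced'`) — C = 1 is deliberate, as much larger C
values push the SVM into a hard-margin regime where class weights stop
mattering on imbalanced data. Evaluation is stratified fourfold
cross-validation, seeded and deterministic; the confusion matrix comes
from out-of-fold predictions. Labels under 5 px are excluded from
feature extraction and logged. Mitotic fraction excludes artefacts from
the denominator; total cell counts are normalized to the negative
control (= 1) per time point.

## Expression

Processing order is fixed: MAD filter → probe averaging → quantile
normalization → fold change. The MAD cut is the bare rule
|x − median| / MAD > 2.5 with the *unscaled* MAD (no 1.4826 factor).
Users should know this trims about 9% of perfectly well-behaved
lognormal values (ordinary tails) in addition to gross outliers; the
trimming is symmetric and leaves group means unbiased at the percent
level. When MAD = 0, values deviating by more than 1e-9 are removed and
the event logged. Filtering operates per transcript within each array —
the natural grouping for replicate-bead summarisation.

Quantile normalization replaces each column's sorted values with the
across-column mean of sorted values, ties resolved by averaging tied
ranks. It is applied to the transcript × array matrix (post-averaging).
Fold changes are signed linear (r or −1/r, |FC| ≥ 1 always,
antisymmetric under swapping test and control); the dispersion statistic
is (test − control)/(SD_test + SD_control), reported as missing when
both replicate SDs are zero — routine after quantile normalization when
a transcript holds the same rank on every array.

qPCR: technical replicates are averaged per (gene, condition) before
ΔCt = Ct_target − Ct_reference; ΔΔCt = ΔCt_test − ΔCt_control; relative
expression 2^−ΔΔCt. At zero noise the planted value is recovered
exactly.

## Seed scanning

Scanning is exact string matching of the 7-nt site motif (the reverse
complement of the miRNA seed), not a heuristic alignment: for a fixed
7-mer with one constrained-mismatch rule, direct scanning is complete
and reproducible. The default `pos1_tolerant` policy frees motif
position 1 (opposite miRNA position 8) and requires positions 2–7 — the
CACUUU core for the miR-17 family — to match exactly; `exact` requires
all seven. Overlapping sites are counted separately. Sites are assigned
to the region containing their start offset; a site straddling the
CDS/3′UTR boundary therefore counts as CDS. Sites outside every
annotated region land in a reported "unassigned" bucket, which makes
region counts invariant to concatenating unannotated flanks. DNA input
(T) is transparently mapped to RNA. Gene-level presence is "any
variant, any region" by default (restrictable to 3′UTR only).

## Synthetic generators

All generators are seeded (`numpy.random.default_rng`) and bit-exactly
deterministic given spec + seed; every generated entity has exactly one
ground-truth record.

**Nuclei fields** (default 1024×1024, 100 nuclei). Interphase: smooth
ellipses (semi-axes 7–13 px); mitosis: small condensed shapes at 2.2×
interphase brightness; apoptosis: 3–5 small fragments sharing one label;
artefact: two fused elongated ellipses (the multi/binucleated catch-all).
Centers are rejection-sampled with a 42 px minimum distance so nuclei
never touch — segmentation ground truth stays unambiguous while still
testing proximity. Background is a plane gradient (amplitude 150 counts
over a 300-count base) plus Gaussian read-out noise (SD 40); intensities
are 16-bit unsigned. Not emulated: optics/PSF, chromatin texture,
overlapping nuclei, 3-D structure — so a high synthetic segmentation or
classification score bounds algorithmic correctness, not real-image
performance.

**Uptake screens.** Per-cell uptake is lognormal (sigma 0.5) around a
true well median; negative-control wells sit at 1000 a.u. with
well-to-well SD 80 (8%); a planted effect `e` shifts the well median by
`e` times the *total* control well SD (biological plus the analytic
sampling error of a 200-cell median), so the normalized score is
calibrated to recover `e` directly. Defaults — 8 negative-control
wells, duplicate wells per test condition, 3 experiments, 200 cells per
well — are a realistic slide-based layout under which a planted −3 SD
effect is called essentially always and null conditions stay within the
gated 5% false-call rate. The lognormal choice for per-cell uptake is a
modelling decision (integrated endosomal intensities are right-skewed),
not a measured fact. Rendered wells place each cell's uptake as
Gaussian puncta (sigma 1.5 px) in a 12–18 px annulus around its nucleus;
puncta integrate to the cell's true uptake up to 16-bit discretisation
of faint tails (a few percent), which is why image-based recovery is
tested at ~10% tolerance while table-based statistics are exact.

**Transcriptomes.** Background sequence is uniform random RNA with any
occurrence of the 6-mer site core resampled away, so planted site counts
are exact by construction; after planting, the generator verifies that a
scan finds exactly the planted coordinates and regenerates the
transcript otherwise. CDS lengths are multiples of 3. Only the
requested motif's core is excluded from the background — unrelated
motifs can appear by chance, as in real sequence.

**Expression datasets.** Probes emulate replicate beads of one probe
sequence per transcript (26 by default): intensity = transcript baseline
× planted fold (test arrays) × bead affinity (lognormal sigma 0.05) ×
array scale (sigma 0.1, what quantile normalization removes) × bead
noise (sigma 0.2), with 2% gross outlier beads at ±8×. Transcript
baselines are lognormal (sigma 0.8) over a 200-transcript simulation;
transcripts carrying planted fold changes are drawn from the quantifiable
dynamic range (between roughly the 16th and 98th baseline percentile),
because a fold change of a floor-level transcript is unmeasurable by
rank-based normalization and the brightest signals saturate real
scanners — mirroring the fact that published hit lists come from
in-range signals. With only 200 transcripts, quantile normalization has
coarse rank resolution in the distribution tails; real arrays have two
orders of magnitude more probes and correspondingly finer resolution.

**qPCR.** Reference gene at Ct 20, target control at Ct 24, planted ΔΔCt
added to the target's test condition; Gaussian noise on the Ct scale per
technical replicate (default 4 = 2 RT × 2 PCR).

## Problem sizes and numerical choices

The test suite and acceptance script use: 500-screen Monte Carlo for
power and false-call rates; a 200-transcript × 12-array expression
simulation; 800 nuclei (~200 per class) for classifier training; one
100-nucleus field for segmentation scoring; 1000 random sequences for
scanner/oracle equivalence. Matching of segmented to ground-truth
objects uses IoU > 0.5. Ties in quantile normalization are averaged;
ties in region expansion go to the nearest nucleus with label-order
tie-break; blank images segment to an empty mask rather than an error.

## Known limitations

No illumination-correction or flat-field model; no 3-D, time-lapse or
tracking; no plate-position (edge-effect) correction or B-score
alternatives; no multiple-testing correction across screen conditions or
transcripts (the workflow uses fixed fold-change and score cut-offs);
seed scanning does no thermodynamic or conservation scoring — presence
of a seed-matched site is necessary, not sufficient, for targeting.
Classifier and segmentation scores on synthetic fields validate the
implementation, not performance on real micrographs.
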