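# Methods

This note documents the models, numerical choices and known limitations of
`batmri`. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`; nothing is asserted from memory.

## Signal model and water–fat separation

A voxel with total magnitude signal `S` and fat fraction `ff` contributes
water `W = S·(1−ff)` and fat `F = S·ff`. The two-point chemical-shift
acquisition observes the in-phase echo `IP = W + F` and the opposed-phase
echo `OP = |W − F|`, each with additive Gaussian noise (one tunable SD per
echo, in units of the adipose reference signal; default 0.02, i.e. SNR 50
in adipose tissue). Rician magnitude statistics are not modelled: at the
simulated SNR the Gaussian approximation is excellent, and background air is
never analysed.

Magnitude echoes are symmetric in W and F, so the separation
`dominant = (IP+OP)/2`, `minor = (IP−OP)/2` needs an assignment of which
species dominates each voxel. On a scanner this is resolved from the complex
phase by the vendor reconstruction; `separate_water_fat` therefore accepts
either a global assumption (`'water'` or `'fat'`) or a per-voxel boolean
dominance map. Phantoms ship the true dominance map, standing in for a
correct vendor reconstruction; **fat/water swap artifacts** are simulated by
inverting that map inside declared regions, which exchanges the
reconstructed water and fat there, and are detected downstream as connected
components of genuine signal whose median FF is near-complementary to soft
tissue (≥ 0.80). Swap flagging is advisory; the pipeline excludes a subject
when a flagged component lies within 10 mm of any segmentation seed. Phase
modelling and swap *correction* are out of scope.

The fat signal fraction is `FF = F/(F+W)` on voxels with combined signal
above 10⁻⁶ × image maximum (others are marked invalid rather than evaluated
as 0/0); values are clipped to [0, 1]. This is a two-point signal-fraction
estimate: no multi-peak fat spectrum, T1 bias or T2* correction, and no
noise-bias correction.

## Tissue fat-fraction distributions

Voxelwise FF within a tissue follows a **skew-normal** law, the simplest
family able to match the three statistics available for adipose FF
distributions (mean, SD, skewness). Moments are inverted in closed form
(`skewnorm_params`); |skewness| must stay below the family's supremum
0.99527. Draws are clipped to a tissue-specific band and the clip fraction
reported. Reference distributions (fractions): ex-vivo BAT 0.437 ± 0.078,
skew −0.27; ex-vivo WAT 0.733 ± 0.104, skew −0.85; in-situ counterparts
0.430 ± 0.141 and 0.679 ± 0.156 with skewness left at 0 (not separately
characterized in situ).

A consequence worth knowing: the skew-normal matched to the ex-vivo WAT
moments places 11.4 % of its mass below FF = 0.60 (exact CDF), so the WAT
false-positive rate of the 60 % threshold computed on this reconstruction
slightly exceeds the 10 % figure observed on empirical ex-vivo data, whose
distribution was right-truncated by a maximum observable FF and accordingly
thinner in the left tail. The test suite pins the honest reconstruction
value.

## Phantoms

**Vial phantom** — two ellipsoidal "tubes" (one BAT-like, one WAT-like
distribution) in air on a 64×32×32 grid; used for the ex-vivo contrast and
all round-trip identities.

**Torso phantom** — a 128×96×64 grid at 0.97 × 0.97 × 1 mm (the acquisition
voxel size; the scene can be shrunk with `scale` for fast tests, volumes
scaling with `scale³`). An ellipsoidal water-dominant body (total signal 0.5,
FF 0.06 ± 0.03 clipped below 0.18) carries the analysis depots, all
axis-aligned ellipsoids with analytic volumes:

| depot | location | FF (default) |
|---|---|---|
| supraclavicular L/R | superior–lateral | 0.289 |
| axillary L/R | lateral, inferior to supraclavicular | 0.303 |
| spine T1–T5 L/R | paravertebral, 10 mm level spacing | 0.322 |
| nuchal WAT | posterior subcutaneous bulge | 0.677 |
| subcutaneous pads L/R | anterior chest | 0.45 (fixed 4 cc each) |

BAT voxel FF is clipped to (0.205, 0.595) — BAT is in the 20–60 % band by
construction — and WAT to (0.58, 0.95). Within-depot voxelwise FF SD is not
published for the in-vivo setting; defaults are 0.04 (BAT) and 0.05 (WAT),
small enough that band clipping moves depot means by < 0.3 pp. The anterior
pads are not analysis regions: they give the appreciable-signal mask the
moderate-fat tissue a real torso has, which anchors the lowest-quartile fat
threshold of the WAT protocol below WAT fat levels for every cohort draw
(without them, a subject with small BAT depots can push that quartile into
the WAT range and invalidate the nuchal seed).

Depot overlap is checked voxelwise at paint time; analytic ellipsoid volume
versus voxelized volume is verified within a one-voxel shell. Canonical
("rater 0") seeds sit at depot centroids: 3 mm bubbles for BAT, 5 mm for
nuchal WAT. Raters are emulated by isotropic Gaussian seed jitter whose
per-axis SD is set so the expected displacement norm equals the requested
magnitude (chi-3 mean, `sigma = m/(2√(2/π))`), redrawn until the seed stays
in its depot.

**Cohorts** — per-subject true parameters are drawn from between-subject
distributions: combined supraclavicular+axillary (union) volume
6.50 ± 3.10 cc truncated to [1, 15] cc and split at the mean-volume ratio
2.95 : 3.76; spinal volume 3.65 ± 1.40 cc; regional BAT FFs 0.289 ± 0.040 /
0.303 ± 0.033 / 0.322 ± 0.032 truncated to [0.215, 0.55]; nuchal WAT FF
0.677 ± 0.046 truncated to [0.58, 0.90]. The nuchal depot volume is not a
published cohort statistic; 5.0 ± 1.5 cc is used. Draws are **stratified**
by default (inverse-CDF at independently permuted stratified uniforms) so
that a 22-subject cohort's sample moments track the population values —
the cohort is meant to *be* the stated population, not an arbitrary draw
from it; `stratified=False` gives iid draws.

**Rescans** re-emit echoes from the same noiseless truth with fresh noise
and, optionally, a smooth multiplicative gain field (Gaussian-filtered white
noise, 25 mm correlation length, peak amplitude configurable) emulating
independent shim/pre-scan calibration. No registration is applied anywhere.

## Segmentation

The semi-automated protocol is implemented as monotone morphological region
growing: the eligibility set is `{0.20 ≤ FF ≤ 0.60}` ∩ validity ∩
appreciable signal for BAT, and `fat > Q1(fat within signal mask)` for
nuchal WAT; each iteration adds at most one 26-connected voxel shell of
eligible neighbours, then drops candidates supported by fewer than 4 of
their 26 neighbours (a curvature-like smoothing that suppresses one-voxel
tendrils; if smoothing would stall growth entirely the unsmoothed shell is
kept). Iterations map one-to-one to shells, so the protocol's iteration
count is the stopping rule: 50 for supraclavicular and axillary, 50 for
spine (configurable 40–60), 100 for WAT. Components not containing a seed
are discarded. Seed-count limits are enforced (≤ 4 per side for
supraclavicular and axillary; exactly one per side per vertebra, T1–T5
only; a single 5 mm WAT seed). A continuous level-set evolution was
deliberately not used: the iteration-to-shell mapping is reproducible,
dependency-light and has the same confinement semantics.

Coordinates are plain: voxel (i,j,k) has its center at index × spacing; no
orientation matrices. Seed bubbles are spheres in physical mm (anisotropic
voxels respected). The pipeline snaps BAT seeds to the nearest in-band voxel
within 3 mm before segmenting — the automated analogue of a rater dropping
seeds on voxels that visibly belong to the depot; a truly ineligible seed is
an error naming the seed. A degenerate (constant) fat image makes the WAT
quartile threshold meaningless; it falls back to the signal mask with a
warning. Mean depot FF uses all valid voxels of the final mask without
re-thresholding.

## Quantification and statistics

Volume = voxel count × voxel volume (0.9409 mm³ by default), reported in cc
(= mL); FF reported in percent to one decimal. Cohort summaries use the
sample SD (n−1). The WAT–BAT contrast is the mean of per-subject
(nuchal WAT − union BAT) mean-FF differences with a two-sided paired t test
(Wilcoxon available); the mean paired difference and the difference of means
are both reported (they coincide on complete layouts). Zero-variance
differences are reported as degenerate rather than raising.

Rater reliability uses the two-way random-effects expected-mean-squares
decomposition (single measurement, absolute agreement): σ²_subject =
(MS_subj − MS_err)/k, σ²_rater = (MS_rater − MS_err)/n, σ²_residual =
MS_err; negative estimates truncate to 0 and the shares renormalize, so
ICC + WSC + N = 1 exactly and each lies in [0, 1]. Without truncation the
subject share equals the classical ICC(2,1), which the tests cross-check
against an independent implementation. With three ratings (rater 1 twice:
1a, 1b; rater 2 once) the inter-rater ICC is the average of the pairwise
(1a vs 2) and (1b vs 2) decompositions and the intra-rater ICC is
(1a vs 1b) — averaged pairwise, not a three-rater model.

Scan–rescan agreement is the Pearson correlation (linear, per the scatter
being summarized) of jointly valid voxel FFs per compartment (BAT union,
nuchal WAT, all other appreciable-signal voxels) plus the mean absolute FF
residual in percentage points; compartments under 10 voxels are skipped with
a warning. ROC calibration sweeps FF thresholds at 0.001 granularity; the
upper threshold is the largest cut with WAT false-positive rate < 10 %, the
lower the largest cut keeping ≥ 99.9 % of BAT above it; AUC is the pairwise
probability P(BAT FF < WAT FF) on small samples (trapezoid on large ones).

## The BAT candidate mask

The three-criterion visualization rule keeps voxels with (1) total signal
> mean + 2 SD of the whole image, (2) a fat-signal criterion "one SD below
the image mean", and (3) FF > 20 %. Criterion 2 is grammatically ambiguous;
the default reads it as an *upper* bound (fat < mean − SD; BAT is fat-poor
relative to WAT), with the lower-bound reading available via
`fat_criterion='above'`. Note the structural caveat: criteria 1 and 2 pull
in opposite directions — criterion 1 needs a mostly-dark total image, which
forces the fat image's mean − SD below zero (for a mostly-zero fat image,
mean − SD > 0 requires fat-bright voxels to exceed half the image), making
the default criterion 2 empty on whole-torso images. The thresholds actually
applied are stored on the result so this degeneracy is visible; the mask is
a QC aid, never the analysis ROI.

## What the phantoms do and do not show

Passing tests demonstrate that the measurement chain is unbiased and
reliable *given the model*: ellipsoidal depots with sharp boundaries,
piecewise-constant total signal, Gaussian echo noise, skew-normal FF
texture, perfect scan–rescan geometry. Real neonatal data add partial-volume
mixing at depot borders (WAT interspersed in BAT is explicitly not
corrected), coil-profile shading, motion, multi-peak fat chemistry and
relaxation effects — none of which are simulated. Scan–rescan correlations
and residuals depend on the chosen noise SD and are therefore exercised as
machinery (identity, symmetry, Monte-Carlo consistency), not pinned to
specific published values.

## Problem sizes

Default analyses run at the full 128×96×64 torso grid; 22-subject cohort
generation + segmentation + quantification takes well under a minute.
Unit tests use a 0.55-scaled scene (70×53×35) for speed. Threshold
operating points use 10⁶ draws.
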