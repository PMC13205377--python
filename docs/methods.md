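# Methods

This note documents the models behind `pigtme`, the choices made where the
design was genuinely open, and what the synthetic cohorts do and do not
establish about real data.

## The question

Scale BW and image-derived BW are treated as two measurements of one
genetic character. If the vision system's error is exchangeable noise, the
trait measurement error `TME = |scale − image|` has no additive genetic
variance, heritability estimates for the two measurements agree, and the
markers that top the scale-BW association scan also rank highly for image
BW but not for TME. The interesting alternative is a *systematic* error
channel: depth-based volumetrics assume a constant ground-to-ventral-
abdomen gap (the "clearance"), so clearance-raising alleles would inflate
height and volume for carriers and make TME heritable. The package
simulates both worlds and runs the full genetic analysis on each.

## Synthetic cohorts

**Genotypes.** `m` unlinked biallelic SNPs with allele frequencies drawn
from U(maf_low, maf_high) = U(0.05, 0.5). Two population designs:

- *half-sib families* (default, `n_sires = 25`): sires are drawn from
  Hardy–Weinberg proportions; each offspring receives one sire gamete and
  one dam-population gamete, giving paternal half-sib families of n/25
  animals with relatedness 1/4 and unchanged marginal frequencies. This is
  the structure of a sired commercial finishing batch, and it is what
  makes REML informative: with completely unrelated animals at
  n = 800, m = 10,000, G ≈ I and the standard error of ĥ² is ≈ 0.18, too
  wide for any null/alternative contrast. With 25 sires the SE is ≈ 0.04,
  matching what field studies of this size report.
- *unrelated* (`n_sires = None`): independent Binomial(2, p) per animal;
  used where the estimator itself (frequency sampling, GWAS power) is the
  object of study.

No linkage disequilibrium is simulated; marker effects are therefore only
taggable through the causal markers themselves, which is why causal
variants are always drawn from the post-MAF-filter frequency range.

**Scale BW.** `scale_bw = mean_bw + Xb + u + ε`, with 10 QTL sampled
without replacement, equal expected variance per QTL and random sign,
rescaled so the realized var(u) is exactly `h2_bw · sd_bw²` (default
0.4 · 12² kg²); ε ~ N(0, (1−h2_bw) sd_bw²). Fixed effects (sex, birth
farm, pen density, age, parity of dam) are small centered shifts, a few kg
at most, re-estimated by every downstream model. Cohort means per farm
visit are 65/78/92/114 kg (T1–T4); across visits the QTL set and breeding
values are held fixed and residuals are redrawn.

**Ventral clearance.** `clearance = 0.17 m + g + e`, truncated at 0, with
total SD 0.02 m split by `h2_clearance`. The genetic part is deliberately
*carrier-like*: a single QTL whose counted allele is rare (frequency in
[0.05, 0.06]) and clearance-raising. This matters because TME is an
absolute value: for a symmetric polygenic clearance, E[TME | g] is an even
function of g and its additive projection is ≈ 0 — a symmetric
architecture cannot make |error| heritable no matter how heritable the
clearance is. A rare, positive-effect variant puts carriers in one tail
(large one-sided errors) and keeps the additive signal. The lower bound of
the frequency window coincides with the MAF filter threshold (both use the
same observed frequencies), so the causal variant always survives
filtering.

**Bodies and images.** Bodies are half-ellipsoids: linear dimensions scale
as `coef · BW^(1/3)` (length/width/height coefficients 0.28/0.082/0.075
m·kg^(−1/3)), floating `clearance` above the floor, with per-animal
conformation scatter (`shape_sd = 0.025`: length and width lognormally
perturbed, height compensating so body volume stays proportional to
mass — longer-leaner versus shorter-rounder animals). The renderer places
the body under a camera 1.40 m overhead (orthographic projection at the
floor-plane scale implied by an 87° horizontal field of view), adds
per-frame pose jitter, head/tail protrusions, and sparse depth dropouts,
and emits a distance map in meters plus a pseudo-color image whose hue is
linear in distance (0° at the camera, 240° at the floor; uint8 RGB
round-trips distance to ≈ 1.5 mm).

**Feature-space mode.** Rendering 800 videos per visit is unnecessary for
the genetics, so large cohorts use closed-form features: the same
trimmed-band geometry the segmenter measures (including the expected
head/tail extents), plus multiplicative measurement noise
(`feature_noise = 0.01` per feature) standing in for residual frame-
sampling variability after the within-video median. The two modes agree
within a few percent on rendered test shapes, which the suite checks.

## Segmentation

Foreground is hue strictly below an adaptive threshold that starts 15°
under the frame's mean hue and climbs in 1° steps (up to mean + 5°) until
the largest 8-connected component's bounding box clears the border by more
than 5 px; a threshold at which essentially the whole frame is foreground
gives no figure/ground separation and counts as empty, so a floor-only
frame reports "no pig" rather than a full-frame blob. The minimum-area
rectangle comes from rotating calipers over the convex hull of boundary-
pixel corners (pixel corners, not centers, so a k-pixel-wide slab measures
exactly k). Head/tail trimming removes `min(trim_ratio · width/length,
0.25)` of the long-axis extent at each end. Features: box sides in pixels;
height = camera height minus the mean masked distance (zeros replaced by
the mean of non-zero masked distances first); volume = per-pixel sum of
heights. Note the average-based height is an *average*: it sits ~15–18%
below apex-height-plus-clearance (the mean of a half-ellipsoid cap), but
two bodies differing only by clearance δ differ in extracted height by
exactly δ — the mechanism that propagates clearance into the features.

## BW regression

OLS and a random forest (500 trees, minimum node size 5, feature-subset
size tuned by seeded 5-fold CV minimizing RMSE) are trained on a
*reference cohort* drawn without clearance genetics and then applied to
the study cohort, so study metrics are fully out of sample. This replaces
an in-cohort 80/20 split deliberately: vision regressions are calibrated
under the constant-clearance assumption, and a model retrained on the
study cohort itself partially *learns around* a clearance shift (the
linear combination `volume − area·height` cancels it), which launders the
failure mode (see below). The third estimator, `volumetric`, is not
statistical at all: it inverts the geometric volume(BW) calibration curve
at the reference clearance, the purest form of the constant-clearance
assumption.

## Quantitative genetics

Markers with MAF < 0.05 are removed (MAF exactly 0.05 is kept);
`G = WW′/m` from columns centered by 2p and scaled by √(2p(1−p)) with
observed frequencies. REML for the one-random-effect GBLUP model is exact:
one eigendecomposition of G, then a bounded Brent search of the profiled
restricted likelihood over log(σ²_u/σ²_ε) in [−10, 10]; endpoints are
boundary estimates and flagged. SE(ĥ²) comes from the inverse expected
information of (σ²_u, σ²_ε) by the delta method. The association scan
holds the null variance components fixed across markers and fits each
(centered) marker by GLS in the rotated, whitened basis, with Wald t-tests
on n − p − 1 degrees of freedom; p-values are computed through the log
survival function so −log10 p is accurate for extreme markers, rankings
break ties by scan order, and markers collinear with the fixed effects are
flagged with p = 1. No multiple-testing correction is applied anywhere:
the analysis compares rank lists (top-10 within top-100), not significance
calls. The per-marker approximation error of the fixed-components device
is bounded in the tests against full per-marker REML refits (within 10% on
top markers).

## The two scenarios, and what they show

*Random error* (`h2_clearance = 0`): TME heritability estimates pile up at
the boundary (ĥ² ≤ 0.05 in ≈ 95% of replicates, mean ≈ 0.01), agreement is
10/10, TME overlap 0/10. *Heritable clearance* (`h2_clearance = 0.5`,
volumetric estimation): ĥ²_TME averages ≈ 0.35 (replicates span roughly
0.2–0.6, the range reported for image-derived biomass/height traits in
crops), demonstrating that the null result is a property of the error
structure, not of the pipeline's inability to detect genetic error.

A genuinely informative negative finding from building this: when the
4-feature OLS/RF regression is *trained on the study cohort itself*, it
partially absorbs the clearance dimension and ĥ²_TME drops to ≈ 0.1 even
in the heritable-clearance world. Trained regressions launder systematic
error into apparent noise; assumption-laden model-based estimators do not.
Both behaviors are real and reproducible with the package.

## Numerical choices and scales

- Test/default image scale is 320×180 px, 20 frames/video; full 1280×720
  at 30 fps is supported but never required.
- Default cohort n = 800, m = 10,000; the REML grid-search cross-check
  runs at n = 200 against a 10⁴-point dense-likelihood grid (agreement to
  1e-3 in h²). Replicated checks (null boundary behavior, recovery of
  h² ∈ {0, 0.25, 0.5}, failure-mode replicates) use 10–20 seeded
  replicates; recovery replicates share one genotype cohort and redraw
  traits, which is the quantity the estimator is conditioned on.
- All randomness flows from one integer seed through
  `numpy.random.SeedSequence` spawns, one stream per stage, so stage
  skipping (e.g. resuming from persisted features) does not shift
  downstream draws.

## Limitations

- Synthetic depth frames are clean geometry; there is no occlusion, no
  multi-animal interaction, no sensor-specific noise model, and the
  quality-control problem real barn footage poses is reduced to the
  segmenter's own drop rules. Passing tests show the analysis chain is
  correct and the two error-structure worlds are distinguishable, not that
  segmentation would survive commercial image quality.
- No linkage disequilibrium and exchangeable family structure: estimates
  of power (e.g. all causal markers in the top 1%) translate to real
  panels only qualitatively.
- The clearance failure mode is demonstrated with a monogenic carrier
  architecture because an absolute-value error statistic is structurally
  blind to symmetric polygenic error genetics; that blindness is itself a
  property worth knowing about TME-style statistics.
- Only absolute (unsigned) TME is analyzed.
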