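# Methods

This note records the models, estimators, numerical choices, and known
limitations of `spheroscreen`, stage by stage.

## Synthetic assay generator (`simgen`)

The generator stands in for a droplet-based spheroid screen. Each spheroid
is assigned a latent viability that follows the variable-slope sigmoid
`v(c) = 100 / (1 + (IC50/c)^h)` with `h < 0`, plus Gaussian jitter
(sd 5 percentage points, clipped to [0, 100]). Drug action builds up over
time: at timepoint `t` the effective IC50 is
`IC50 · f^(1 − t/48)` with `f = 2.5`, so the 24 h response is a
right-shifted version of the 48 h curve and the 0 h viability is always
100%. This is what makes time-shifted prediction (train at 48 h, predict
from 24 h features) produce IC50 estimates at or above the 48 h value.

Morphology is a deterministic monotone function of viability plus jitter —
the design requirement is that features carry class information while the
ground truth stays analytically known:

- radius: `r0 · (1 + (t/48)(0.5·v/100 − 0.3·(1 − v/100)))` with
  `r0 ~ N(140, 8)` μm — healthy spheroids grow ~1.5× by 48 h, dead ones
  shrink ~30%;
- interior intensity: `150 − 55·(1 − v/100)·(t/48)` (8-bit scale,
  background 200) — dying spheroids darken;
- texture roughness: `0.06 + 0.22·(1 − v/100)·(t/48)` — dying spheroids
  grow coarser internal grain.

Batch effects are additive per-experiment offsets on image intensity
(sd 6 gray levels) and a multiplicative log-normal gain (sd 0.10) on
fluorescence — these are what leave-one-experiment-out validation has to
survive. Rendering produces 8-bit focal stacks (5 frames, 25 μm apart,
3.26 μm/pixel, 160×160): one frame is in focus, the others are Gaussian-
blurred by 1.5 px per frame of focal distance; the spheroid is an
antialiased dark disk with a smooth multiplicative grain field; pixel noise
sd 3. A configurable fraction (default 7.5%) of droplets contain two
sibling spheroids at 0 h whose radii split the fused volume
(`r_i = r·f_i^{1/3}`), fused from 24 h on — exactly the geometry the
area-fusion rule `(Σ A_i^{3/2})^{2/3}` inverts.

Fluorescence readouts are `B + (v/100)(C_e − B) + N(0, 60)` with basal
`B = 100` and per-experiment control level `C_e`; each experiment also gets
8 basal-only droplets. With the noise set to zero the readout→activity
mapping is exactly invertible, which the round-trip tests exploit.

Default problem size: 9 dose conditions (0 plus 0.1–50 μM), 6 replicates,
3 experiments — 162 spheroids, ~490 stacks per assay. This desk-scale
default keeps a full pipeline run around 20 s; all rates and noise levels
above are independent of it.

What the generator does **not** emulate: droplet optics and menisci, debris
and segmentation-defeating artifacts, unfused multi-spheroid droplets at
later timepoints, spatial fluorescence images (readouts are scalars), or
biological heterogeneity beyond a single Gaussian jitter per quantity.
Passing tests therefore show the pipeline is correct and well-calibrated on
this model of the data, not that it is robust to every real-world imaging
failure; the manual spheroid-location step used with real plate-reader data
is replaced by automatic detection.

## Imaging

Focus selection scores each frame by the variance of its Laplacian and
takes the argmax (ties → lowest index). Segmentation: Canny on the
2 px-Gaussian-smoothed image with hysteresis thresholds from the gradient
distribution — upper = max(90th percentile of nonzero magnitudes, 0.4 ×
99.5th percentile), lower = upper/2. The percentile floor matters when a
small object sits in a large noisy background, where the plain 90th
percentile collapses to the noise level. Edges are closed (disk 3), filled,
and components below the area of a 20 μm-diameter disk discarded.

The filled Canny contour carries a systematic half-pixel outward bias (the
edge line itself is part of the fill), which alone is a +5% area error for
a 20 px radius. The mask is therefore refined to the half-height intensity
level: threshold midway between interior and background medians, within a
3 px band around the coarse mask, followed by a light closing/opening
(disk 2) to remove texture-induced boundary raggedness. On rendered disks
of radius 20–80 px across contrasts 40–120 and noise sd 0–5, recovered
areas are within 5% and circularities within 0.1 of the ideal in 225/225
cases.

Perimeter uses the Crofton estimator (4 directions). This choice is fixed
because circularity on a pixel grid depends entirely on the perimeter
estimator: Crofton gives rasterized disks circularity 0.97–0.99, while
marching-squares contour length gives 0.87–0.89 (and the naive boundary
count even less), i.e. only Crofton keeps the circle near its analytic
value of 1. The cost is a known upward bias for axis-aligned rectangles
(square ≈ 0.88 vs π/4 ≈ 0.785) — acceptable, since spheroids are round.
A perimeter floor of 1 px avoids division by zero on degenerate masks.

## Features

- Area `n_px · pixel_size²`; equivalent-disk diameter `2√(area/π)` (Table-
  style "diameter" is otherwise undefined, and the equivalent diameter is
  the one consistent with area-based fusion).
- Mean gray: mask eroded by 3 px (fixed, testable version of "exclude the
  edges"), minus the mean outside the mask; negative for dark spheroids,
  invariant to global intensity shifts. If erosion empties the mask the
  un-eroded mask is used and a warning logged.
- GLCM: masked pixels quantized to 32 levels over the region's own range;
  symmetric normalized co-occurrence at distance 1 for angles
  0/45/90/135°, restricted to pixel pairs entirely inside the mask;
  homogeneity `Σ P/(1+|i−j|)`, energy `Σ P²`, correlation
  `Σ P(i−μ)(j−μ)/σ²`, averaged over angles. Constant regions return
  correlation 0 by convention; regions without a single valid pair are
  marked missing. scikit-image's `graycomatrix` cannot restrict pairs to a
  mask, so the matrix accumulation is implemented here and verified against
  a brute-force pair-enumeration oracle (exhaustively for small binary
  images).
- Multi-spheroid fusion: area by `(Σ A_i^{3/2})^{2/3}` (volume-conserving
  for spherical aggregates), diameter recomputed from the fused area,
  everything else (including perimeter) arithmetic means.
- Temporal: Δgray(t₂−t₁) and growth `(area₄₈ − area₀)/area₀` (relative, so
  comparable across spheroid sizes).
- Rows missing any selected feature are excluded from the table; no
  imputation. Standardization is *not* part of the table: the classifier
  fits its scaler on training folds only.

Solidity is area over convex-hull area. For a plus-sign of five unit
squares the true hull is the enclosing square minus four corner triangles
(area 7), giving 5/7 ≈ 0.714 — not the 5/9 a bounding-box reading would
suggest; the tests assert the hull geometry.

## Viability

Normalization estimates `B` as the mean of the basal-only droplets and the
control level as the mean of the no-drug droplets, both **per experiment**
(batch gains make pooling incorrect). Values outside [0, 100] are kept;
the no-drug spread itself is informative. Class thresholds use strict
inequalities exactly as stated ("below 50%" → low), so boundary values go
to the non-strict side; with continuous noise this is a measure-zero
choice. A control mean at or below basal raises a degenerate-assay error.

## Feature ranking

MI is estimated by equal-frequency binning of the feature
(`⌈√(n/5)⌉` bins, capped at 16; features with fewer distinct values keep
their own categories), plug-in entropies in bits, minus a permutation
baseline (mean over 100 label shuffles, floored at 0). The baseline removes
the `O((bins−1)(classes−1)/2n ln 2)` positive bias of plug-in MI, so
uninformative features score ≈0 bits instead of the bias floor — important
because real feature/class MIs in this problem are sub-bit. Calibration:
a balanced binary feature flipped with probability 0.1 scores
1 − H₂(0.1) = 0.531 ± 0.02 bits at n = 10⁴; an independent feature ≤ 0.02
bits. Ranking sorts by MI descending, ties broken alphabetically; k > #features
falls back to all with a warning. Only MI ranking is implemented — no
network reconstruction, edge orientation, or latent-variable analysis.

## Classifier

scikit-learn's `MLPClassifier` provides the 128-10 ReLU / softmax /
Adam / cross-entropy architecture; training is driven by an explicit
`partial_fit`-per-epoch loop (150 epochs, batch 16, step size 10⁻³, no
early stopping) so train/test accuracy and loss are recorded every epoch —
the overfitting monitor. Features are z-scored with statistics from the
training fold only. Cross-validation folds are whole experiments;
corrupting test-fold labels provably leaves training untouched (asserted
bitwise in tests). Metrics: accuracy, precision, recall, f1 with "high"
viability as the positive class (macro-averaged for three classes), and
ROC-AUC from the positive-class probability; a single-class test fold gets
AUC = NaN with a warning. One seed controls weight init and batch
shuffling and is recorded in every report. No class reweighting is applied;
imbalance shows up in the per-class metrics instead.

Transfer evaluation applies a fitted model to a second dataset aligned by
feature *name* (column order irrelevant), keeping the source scaler;
missing features raise an error naming them.

## Dose-response fitting

Continuous mode: least squares of `Y = 100/(1 + (IC50/X)^h)` on positive
doses (controls define the plateau through the normalization itself),
initialized at the geometric mean dose and slope −1, bounded to
IC50 ∈ [1e−9, 10⁴], h ∈ [−50, −10⁻³]. Reports Wald 95% intervals from the
fit covariance and R²; R² < 0.5 flags a poor fit, and optimizer failure
returns a flagged fit rather than raising.

Binary mode: Bernoulli likelihood with `p(X) = 1/(1+(IC50/X)^h)`, uniform
priors IC50 ∈ (0, 20] μM and h ∈ [−50, −0.1], sampled with emcee's
affine-invariant ensemble (32 walkers, 500 retained iterations after a
500-iteration burn-in; symmetric split keeps the run cheap and split-chain
agreement was checked during development). Zero-dose rows sit on the upper
plateau; their probability is held at 1 − 10⁻⁹ rather than exactly 1 so a
single misclassified control penalizes the likelihood heavily instead of
annihilating it everywhere. Probabilities are floored at 10⁻¹² in the log
terms. Point estimate and interval are the posterior median and 2.5/97.5
percentiles; everything is deterministic given the seed.

Walkers start in a Gaussian ball (sd = 5% of each prior range) around a
coarse grid maximum-likelihood point, not uniformly over the prior box.
The reason is a stretch-move pathology: when the classifier predicts a
clean step (the typical outcome), the posterior is two orders of magnitude
narrower than the prior, and a walker initialized far away can *never*
reach the cluster — every proposal along the line to a cluster walker
(scale z ∈ [0.5, 2]) lands hundreds of log-units below its current
position, so nothing is accepted and the stranded walker corrupts the
posterior percentiles. The ball initialization removes the failure mode
while the burn-in still erases the initialization's imprint.

An exhaustive grid search over the prior box (`grid_ml_binary`) provides an
independent maximum-likelihood cross-check of the sampler; on identifiable
data the posterior mode matches it to ~0.02 μM.

## Pipeline

One global seed fans out to per-stage seeds (simulation, MI permutations,
classifier, MCMC) through `SeedSequence.spawn`, so stages are independently
reproducible. Runs write features, labels, ranking, predictions, fits, and
a report, plus a manifest with a SHA-256 per output file; re-running an
unchanged configuration is byte-identical. Stage failures abort with the
stage name; artifacts written before the failure remain. Per-stage logs
count excluded spheroids (unusable images, incomplete feature rows).

Time-shifted prediction trains on the 48 h feature columns and predicts
from the 24 h columns mapped by descriptor name; the result is explicitly
labelled as having no ground truth at that timepoint.

## Known limitations

- The generator's class structure is nearly separable at the default noise
  levels, so cross-validated scores saturate near 1.0; the tests assert
  thresholds (f1 ≥ 0.9), not the saturated values.
- Frequentist coverage of the 95% credible interval holds under the
  generator's latent-threshold class model; for raw Bernoulli-logistic data
  on a sparse dose grid, coverage at n = 160 is below nominal (~70%) —
  a property of the design (few doses straddle the IC50), not of the
  sampler, and reproduced by exact numerical integration of the posterior.
- Circularity inherits Crofton's rectangle bias; solidity and circularity
  are unreliable below ~20 px radius.
- MI values depend on the binning rule; rankings are stable but absolute
  bit values should not be compared across estimators.
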