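# Methods

`lipdx` implements a computer-assisted lip-diagnosis pipeline for
Traditional Chinese Medicine (TCM): given a lip photograph against a white
background it produces a binary lip mask, an 84-dimensional descriptor,
feature rankings, and a comparative evaluation of five multi-class
classifiers over the four clinical lip-color classes Deep-red, Red, Purple
and Pale. This note records the model, the parameters that matter, the
numerical conventions, and what the synthetic fixtures do and do not show.

## Segmentation

The lip mask comes from a hybrid region pipeline:

1. **Mean-shift smoothing.** Each pixel is iteratively replaced by the mean
   color of the spatial neighbors (Euclidean window, default radius 8 px)
   whose color lies within a range radius (default 16/255 on the [0, 1]
   scale) of the pixel's current color. Pixels across a strong color edge
   never average together, so flat regions are flattened while the
   lip/background boundary survives. Five iterations suffice in practice;
   the filter is a fixed point on constant images.
2. **Chroma transform.** Segmentation runs on a single scalar plane,
   default **Cr** (BT.601), because lip tissue has the strongest
   lip/background and lip/skin contrast there; any of the 12 supported
   planes can be configured instead.
3. **Otsu initialization.** The threshold maximizing between-class variance
   splits the plane; the upper (high-Cr) side initializes the level set.
   A constant plane is a degenerate input and segmentation fails loudly.
4. **Chan-Vese refinement.** The two-phase piecewise-constant
   Mumford–Shah energy is minimized by level-set evolution
   (scikit-image's solver, initialized with the signed distance to the
   Otsu mask). Defaults mu = 0.25, lambda1 = lambda2 = 1, dt = 0.5,
   tol = 1e-3, max 200 iterations — the standard values from the
   level-set literature; all configurable. Non-convergence returns the
   best mask with `converged=False` and a warning rather than an error.
5. **Cleanup.** Largest connected component plus hole filling (can be
   disabled). The final mask must be nonempty and strictly smaller than
   the frame.

Independently of the geometric mask, a **saturation gate** marks pixels
with HSI saturation strictly above 0.1 as lip candidates: a white
background has saturation 0, so the gate removes background bleed-through.
Feature extraction operates on the intersection of the segmentation mask
and the gate.

## Color conversions

All internal arithmetic is on [0, 1] reals; 8-bit input is divided by 255.
The 12 planes are R, G, B; H, S, I (HSI); Y, Cb, Cr (BT.601 full-range,
the JPEG convention, chosen because consumer-camera JPEGs are the expected
input); and Y, I, Q (NTSC matrix). The duplicated Y/I symbols across
spaces are disambiguated as `Y_cbcr`/`Y_yiq` and `I_hsi`/`I_yiq`. Hue is
computed in degrees by the geometric arccos formula and divided by 360 so
H ∈ [0, 1]. Singularities are fixed deterministically: S = 0 at black and
H = 0 at achromatic pixels, so every plane is finite for every valid image.

## The 84-feature descriptor

* **24 color features** — mean and population variance (divide by N) of
  each of the 12 planes over the gated lip pixels, in the fixed plane
  order.
* **13 texture features** — Haralick statistics of masked, symmetrized
  gray-level co-occurrence matrices: angular second moment, contrast,
  correlation, sum of squares, inverse difference moment, sum average,
  sum variance, sum entropy, entropy, difference variance, difference
  entropy, information measure of correlation (IMC1), and the maximal
  correlation coefficient. Conventions: the gray image is BT.601
  luminance quantized to G = 64 levels over [0, 1]; offsets are distance 1
  at 0°, 45°, 90° and 135°, each matrix symmetrized and normalized to sum
  1, features averaged over the four offsets (Haralick's own convention);
  logarithms are base 2; only pixel pairs with **both** endpoints inside
  the mask are counted (scikit-image's co-occurrence routine cannot mask,
  so the accumulation is done directly). For a degenerate matrix (single
  gray level) the correlation-type features are defined as 0. Keeping
  IMC1 only (not the IMC1/IMC2 pair) is what makes the count exactly 13
  alongside the maximal correlation coefficient.
* **47 moment features** — Zernike magnitudes |Z_nl| of the masked
  luminance. The mask's center of mass is the origin; coordinates are
  divided by R, the mean distance of mask pixels from that center, and
  only pixels mapped inside the unit circle contribute. The basis is
  every (n, l) with 2 ≤ n ≤ 12, 0 ≤ l ≤ n, n − l even — 47 pairs, the
  only parsimonious standard set of that size once n = 0 (a constant) and
  n = 1 (annihilated by mass-centering) are dropped. Magnitudes are used
  because they are the rotation-invariant standard. The construction
  makes the descriptors exactly translation-invariant, exactly
  homogeneous of degree 1 in intensity, and rotation-invariant up to
  pixel-grid discretization.

## Feature selection

* **SVM-RFE** (default): backward elimination removing one feature per
  iteration — the one with the smallest Σ over one-vs-one linear SVMs of
  w_j² — retraining after every removal. Inputs must be standardized.
* **Prediction risk**: with a fitted classifier, a feature's importance is
  the increase in training error when its column is replaced by its mean;
  a constant column has risk exactly 0.
* **mRMR** (MID difference form, chosen over the quotient form for
  robustness when redundancy is near zero): greedy forward selection
  maximizing MI(f; y) − mean MI(f; selected), in bits, on discretized
  features.
* **Information gain**: IG(f) = H(Y) − H(Y|F) in bits, ranked descending;
  equals the MI relevance term, so mRMR's first pick and IG's top pick
  coincide under the same discretizer.

Discretization is 3-bin per-feature quantile binning **fitted on training
folds only**; ties in any ranking break toward the lower feature index, so
every ranking is a deterministic permutation. `choose_subset_size`
evaluates nested prefixes of a ranking by stratified CV accuracy and
returns the smallest prefix within one standard error of the best
(the usual 1-SE rule), along with the accuracy-versus-size curve.

## Classifiers

* **SVM (OVO)**: one soft-margin SVC per unordered class pair
  (poly kernel, degree 3, C = 1, gamma = 1/p — unstated upstream, so the
  common library defaults are used and exposed), combined by majority
  voting. Vote ties fall back to the largest aggregate signed decision
  margin, then to the fixed sorted class order.
* **WSVM**: the same ensemble with per-class penalty multipliers at the
  inverse ratio of the training class sizes, normalized so the largest
  class has weight 1 (sizes 90 vs 12 give the minority a 7.5× penalty).
  With equal class sizes WSVM is exactly SVM.
* **kNN**: Euclidean distance, K = 5 by default; distance ties break by
  training-sample index, vote ties by fixed class order.
* **Naive Bayes**: Gaussian per-feature class conditionals with variance
  flooring (scikit-learn's GaussianNB).
* **MAPLSC** — a *reconstruction*, not a reproduction, of the multi-class
  asymmetric-PLS classifier: per class pair, a 2-component PLS projection
  gives a 1-D latent score; class-conditional Gaussians on that score with
  **equal priors** produce the pairwise probability (the equal-prior
  posterior is the imbalance-aware element: the majority class cannot
  drag the decision threshold toward itself); the K(K−1)/2 pairwise
  probabilities are coupled into K posteriors by the Hastie–Tibshirani
  iterative scheme (posteriors sum to 1 by construction). A singular
  projection falls back to prior-based pairwise probabilities with a
  warning.

## Evaluation protocol

Standardization to zero mean / unit variance is fitted on each training
fold and replayed on the test fold (constant columns pass through with
scale 1). The harness runs stratified 10-fold CV repeated R times
(R = 50 at full scale); feature ranking is recomputed **inside every
training fold** to avoid selection bias. Stratification is used even
though plain 10-fold would be defensible: with only 12 Pale samples,
unstratified folds can lose a class entirely. Accuracies are aggregated
per repeat (total accuracy and per-class recall from the repeat's pooled
confusion matrix) and reported as mean ± variance across the repeat-level
values, which matches the magnitude of variance a repeated-CV table
reports. Same seed ⇒ bit-identical report.

Classifiers are compared pairwise on the repeat-level total accuracies
with a Welch two-sample t-test at alpha = 0.05 (the corrected resampled
t-test, which inflates the variance by the test/train ratio to account
for the dependence among CV repeats, is available as an option — the
plain test is anticonservative on repeated CV and is the default only
because it is the conventional choice in this comparative design). Every
significant pair transfers one point: +1 to the winner, −1 to the loser,
so scores within a condition sum to zero; the total rank accumulates the
scores over all feature-selection conditions.

## Synthetic fixtures

`make_lip_image` draws an ellipse (randomized axes 16–22 × 9–14 px,
rotation ±25°, center jitter ±4 px in a 64×64 frame) filled with a
class-specific color — caricatures of the four classes: dark red
(0.45, 0.05, 0.10), bright red (0.80, 0.15, 0.20), violet
(0.45, 0.10, 0.45), pink-white (0.92, 0.62, 0.62) — modulated by a smooth
sinusoidal texture field (amplitude 0.05) and Gaussian color noise
(sd 0.02), on a white background with *achromatic* noise (sd 0.01), which
keeps background saturation at 0 so the saturation gate excludes it by
construction. Default counts mirror the clinical imbalance
(90/12/62/93). `make_feature_table` emits labeled Gaussian tables with a
declared set of informative columns (class-mean separation at effect size
2.0, re-drawn until no two classes collide within 0.8 effect sizes) for
fast selection/classifier tests.

What the fixtures do **not** emulate: real lip geometry (no cupid's bow,
no mouth opening), skin surrounding the lip (background is white, as in
the acquisition-box setting), illumination variation, camera noise
statistics, or the subtle color overlap between clinical classes. Passing
the end-to-end fixture tests therefore demonstrates that the pipeline's
plumbing, invariances and protocol are correct — not that clinical
accuracy on real lips is reproduced; clinical-scale accuracies would
require the original image set.

## Problem sizes in the shipped checks

The test suite and the acceptance script run the full 257-image fixture
set at 64×64 resolution, 10 repeats of 10-fold CV for the in-fold-RFE
experiment and single 10-fold passes across 5 seeds for the SVM/WSVM
imbalance comparison; selection-recovery rates use 100 seeded tables.
These sizes keep a complete run to a few minutes on one CPU while leaving
every protocol element (stratification, in-fold selection, repeat-level
aggregation) identical to the full-scale design; the repeat count is the
one knob reduced from the 50-repeat full protocol.

## Known limitations

* The Chan-Vese stopping rule is the level-set solver's tolerance on the
  evolving function, not literally a relative mask-change criterion; on
  easy fixtures the solver may report non-convergence after the mask has
  long stabilized, which is why the non-convergence path is a warning.
* MAPLSC follows the published *idea* (asymmetric PLS pairwise scorers +
  coupling); internal details of the original are not public, so numeric
  agreement with it cannot be claimed.
* The Welch test on repeat-level CV accuracies ignores the dependence
  between repeats (all repeats reuse the same 257 samples); use the
  corrected variant for honest p-values.
* Information-theoretic rankers see only the discretized features; with 3
  quantile bins, very fine-grained effects can be washed out.
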