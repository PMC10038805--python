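# Methods

This note documents the models implemented in `braincast`, the assumptions
behind the synthetic-data generator, the numerical choices that matter, and
the limits of what the test suite demonstrates.

## Encoding model

The brain score of a feature space X for subject s and voxel v is

    R(s,v) = corr(W·X, Y(s,v))

estimated with five **contiguous** outer folds of the scan series.
Contiguity matters: BOLD is strongly autocorrelated, and interleaved folds
would leak temporal context between train and test. Within each training
fold the features are standardised, reduced to 20 principal components,
and mapped to each voxel by ridge regression; the penalty is selected per
voxel by exact leave-one-out error over ten values log-spaced between
10⁻¹ and 10⁸, then the weights are refitted at the chosen penalty. The
standardiser and PCA are fitted on training rows only. Targets are centred
on the training fold and the ridge carries no intercept — with an
intercept, the closed-form leave-one-out identity is only approximate,
and we test the identity against brute-force refits at 10⁻⁸.

Word-level features reach the scan grid in two steps: activations of words
whose onset falls in the same TR bin (half-open, `[t·tr, (t+1)·tr)`) are
summed, and the pooled matrix is expanded with a 6-delay FIR basis
(lags 0–7.5 s at TR = 1.5 s). The FIR plays the role of a hemodynamic
model without committing to a canonical response shape: each voxel learns
its own lag profile. A fold with a constant prediction scores 0 (with a
warning); a zero-variance test voxel scores NaN and is flagged.

## Forecast windows and maps

The forecast window X̃⁽ᵈ⁾ concatenates the activations of w = 7 consecutive
words ending d words after the current word; entries outside the story are
zero-filled and windows never cross story boundaries. The forecast score

    F⁽ᵈ⁾ = R(X ⊕ X̃⁽ᵈ⁾) − R(X)

uses a separate standardiser + PCA per block before concatenation, so the
present-word block and the window block contribute equally many components,
and both terms of the difference share the same folds. d\* and k\* are
argmaxes over the distance grid [−10, 30] and depth grid [0, 12]; ties
break toward the smallest value for determinism. Because the argmax of a
flat curve is noise, distance and depth maps carry a mask from the
across-subject F⁽⁸⁾ − F⁽⁰⁾ contrast (signed-rank + BH-FDR at p < 0.01).
With eight subjects the exact signed-rank test has a two-sided p floor of
2/2⁸ ≈ 0.0078, so after FDR across hundreds of voxels the 0.01 threshold is
only reachable when most voxels carry true effects — at desk scale the mask
mainly certifies that *null* voxels are excluded.

## Synthetic data: what it emulates

The generator plants known structure so every downstream stage has a
ground-truth recovery test.

* **Stimulus** — word streams at 2.54 words/s by default (gamma-distributed
  gaps rescaled so each story of m words lasts exactly m/rate seconds),
  split into stories separated by 3 s of silence on one timeline.
* **Embedding hierarchy** — layer 0 is word-wise white noise e. Layer k ≥ 1
  mixes a depth-indexed latent stream u_k = √(1−η)·e + √η·f_k (η = 0.8;
  f_k an AR(1) across depth with coefficient 0.7) with its causal moving
  average over the last k+1 words, the smoothed part growing linearly up to
  half the variance at the deepest layer. This reproduces the two facts the
  analyses rely on: deeper layers are more contextual (lag-1 word
  autocorrelation grows strictly with k), and each depth carries content
  that other depths cannot linearly span. Both ingredients are necessary
  for depth to be *identifiable*: if deep layers were exact moving averages
  of layer 0, short windows of shallow activations (plus FIR lags) would
  span them linearly; if deep layers were fully smoothed, lagged
  present-word features alone would predict them and the forecast gain
  would vanish.
* **BOLD forward model** — a planted voxel reads a fixed random linear
  functional of the *window* of 7 embeddings ending `planted_distance`
  words ahead (mirroring the window construct the analysis searches for;
  a single-word readout would sit in every window covering it and leave
  the distance identifiable only up to a 7-word plateau), pooled to the
  scan grid, standardised, and delayed by a pure lag of 3 scans (≈4.5 s).
  A pure lag rather than an HRF kernel keeps the FIR stage the correct
  inverse. Subject s sees √ρ·shared + √(1−ρ)·private times the voxel gain
  (ρ = `shared_signal_fraction`; the private part is a smooth
  stimulus-independent process no feature model can explain) plus white
  noise. Gains are expressed in units of the noise s.d.; the reference
  recovery conditions use gain 5 and noise 1.
* **Tagged language** — words carry (pos, dep) tag pairs drawn i.i.d. from
  a lexicon with ≥ 2 words per pair; a word's embedding is
  syntax_vector(tags) + semantics_vector(word). Tags are sampled rather
  than cycled: a deterministic cyclic grammar would make the syntax stream
  periodic and a planted syntactic distance identifiable only modulo the
  cycle length.

All generators are pure functions of their seed.

## Factorisation

Tag-matched resampling replaces every word by a uniform draw from its
(pos, dep) bucket; averaging activations over n = 10 resampled futures
keeps the tag-determined (syntactic) component plus the bucket-mean
semantics and washes out word-specific content. The residual is the
semantic component, and X = X_syn + X_sem holds to machine precision.
Forecast windows are factorised *after* concatenation: the full window is
built, each future's window is built the same way, and the mean over
futures is the syntactic window. One empirical caution discovered at desk
scale: under the 20-component bottleneck a *clean* component window can
outgain the full window (the other component's dimensions act as
distractors), so the meaningful contract is component selectivity — a
syntax-reading voxel gains more from the syntactic window than from the
semantic one, and vice versa — not an ordering against the full window.

## Noise ceiling

Each subject's BOLD is predicted from the average of the other subjects'
BOLD through the same standardise + PCA + ridge + contiguous-fold scheme.
No FIR is applied (hemodynamic delay is assumed comparable across
subjects). The voxel-space predictor also passes through the 20-component
reduction for comparability with the model features; with many voxels
carrying mutually independent signals this bottleneck can understate the
ceiling, so desk-scale comparisons keep the number of independent planted
signals below the component count.

## Group statistics

One-sample and paired contrasts across subjects use the two-sided Wilcoxon
signed-rank test (all-zero differences give p = 1 with a warning);
independent groups use the rank-sum test. P values are BH-FDR corrected
across voxels or regions and thresholded at corrected p < 0.01; 95%
confidence intervals of the across-subject mean use the t distribution.
Oversized parcellation regions (> 500 vertices) are cut into
⌈n/500⌉ equal slabs along their principal spatial axis (Fiedler-vector
ordering when only adjacency is available); disconnected regions are split
within components, with a warning. ROI summaries report per-subject means
and the distribution over 10 disjoint random subject subdivisions.

## Objective arithmetic

The contrastive predictive-coding loss is standard InfoNCE at temperature
τ = 0.1 with cosine similarity; the denominator includes the positive
term, which keeps the loss non-negative (a negatives-only denominator
turns negative as soon as the prediction beats the negatives). The mixture
weight α′ = α·L_lm / ((1−α)·L_high + α·L_lm) is the unique choice for
which the high-level term contributes exactly the fraction α of the total
α′·L_high + (1−α′)·L_lm for any positive losses — at α = 0.5 both terms
contribute 50%, and α = 0 / α = 1 reduce to the pure objectives. Negatives
are drawn from a queue (default 2,000 of 2,500) without replacement,
excluding the positive's slot.

## Problem sizes and numerical choices

The recovery studies run at 8 subjects, 200 voxels, 4,000 words (~1,060
scans), gains at 5× noise, the full distance grid, and 13 layers; the null
calibration uses ~2,000 scans and 200 voxels. Synthetic embeddings use
U = 4 units in these studies: with the pipeline's fixed 20-component PCA,
a 7-word window design must stay within a few dozen intrinsic dimensions
for the bottleneck to retain the planted readout direction — with wide
embeddings the recovery limit reflects PCA capture noise rather than the
estimator. (Real analyses at U = 768 compensate with hours of stimulus and
hundreds of subjects.) PCA uses a fixed random state; argmax ties break
toward smaller indices; all simulations are seeded.

## What passing tests do and do not show

The generator realises exactly the linear-readout, pure-lag,
additive-noise world the encoding model assumes. Recovery therefore
demonstrates the correctness and calibration of the estimation chain — not
robustness to hemodynamic variability, physiological noise, nonlinear
readouts, or misaligned transcripts, none of which the generator emulates.
File adapters for real datasets (events TSV, HDF5, an optional
transformers-backed activation extractor) are provided but full-scale
replication on real recordings is outside the test scope.
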