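# Methods

## Problem and model

`endo3d` classifies short gastrointestinal endoscopy videos into two
classes — upper GI (esophagus/stomach/duodenum) versus lower GI
(colon/rectum) — from spatiotemporal appearance alone. The classifier is a
3D convolutional network assembled from five *residual-with-parallel-
attention* (RPA) stages separated by four downsampling stages, followed by
global average pooling over time and space and a dense layer emitting raw
two-class logits (the softmax lives inside the loss).

Each RPA stage is a residual block — (2+1)D convolution, channel layer
normalization, ReLU, a second (2+1)D convolution and normalization, plus an
identity (or 1×1×1-projected) skip — whose output passes through a 3D
parallel spatial and channel squeeze-and-excitation module (P-scSE3D).
P-scSE3D combines

* **cSE3D** — global average pooling over (T,H,W), a bottleneck of ratio
  `r` (default 2), and sigmoid gates that rescale each channel, and
* **sSE3D** — a 1×1×1 convolution to one channel whose sigmoid gates every
  spatiotemporal position,

through two parallel branches: a max-out branch `max(c, s)` and an additive
branch `c + s`, summed. Below a channel-count threshold (default 32) the
max-out branch is bypassed ("shorted" form), since max-out over very few
feature maps adds little.

Every convolution is factorized (2+1)D: a 1×k×k spatial convolution into
`M` intermediate channels followed by a t×1×1 temporal convolution
(defaults k = t = 3). `M` defaults to the parameter-matching rule
`floor(t·k²·C_in·C_out / (k²·C_in + t·C_out))`, decremented when the
division is exact so the factorization is always *strictly* cheaper than
the full 3D convolution it replaces.

The numerical core is a small reverse-mode layer library on NumPy
(`endo3d.nn`): convolutions are evaluated as windowed tensor contractions,
and every backward pass is validated against central finite differences in
the test suite.

## Segment sampling

Videos vary from seconds to minutes, so the network consumes fixed-size
*segments*: N frames at a constant index stride G, spanning S = G·N raw
frames (e.g. N = 10, G = 15 spans 150 frames). Starts may fall anywhere in
the video during training; a segment that runs past the end is completed
with all-zero frames, and every segment retains at least one real frame.
At prediction time a video is covered by its ceil(T/S) non-overlapping
span-aligned windows; up to 10 windows are drawn without replacement and
the video score is the mean positive-class (upper-GI) probability over
them, ties resolving to the positive class.

## Experimental protocol

The reference corpus is heavily imbalanced (few upper, many lower videos),
so each experimental run uses *all* upper videos plus an equal-sized random
subset of lower videos. Subsets are a pure function of the master seed and
are therefore identical across architecture and segment configurations.
Runs split their videos 70:15:15 at the video level, stratified by class
(with balanced 60+60-video runs an unstratified 15 % draw could be heavily
skewed); per-class train/validation sizes are `round(r·n)` and the test
split takes the remainder. Training uses Adam (default learning rate 1e-4,
batch 2, 50 epochs — the full-scale settings), softmax cross-entropy on
raw logits via log-sum-exp, one freshly sampled segment per training video
per epoch, and one random segment per validation video per epoch;
final-epoch weights are used (no checkpoint selection). Multi-run summaries
report per-metric means, Student-t 95 % confidence intervals, extremes, and
the histogram of per-run incorrect-prediction counts. The attention
ablation replaces each RPA block by its residual block alone at identical
depth/width and is judged by a paired two-sided t-test and a Wilcoxon
signed-rank test on per-run accuracies (zero differences dropped, mid-rank
ties, exact rank-sum null up to 25 pairs, continuity-corrected normal
approximation beyond).

## Synthetic corpus

`endo3d.synthgi` generates endoscopy-*like* videos, not photorealistic
ones: a bright circular field of view with exactly-black corners, a reddish
smooth drifting texture (upper) versus a pinkish concentric fold pattern
(lower), per-pixel Gaussian noise (sd 0.03), smooth temporal drift, and
uniformly drawn lengths. The default desk-scale corpus is 6 upper / 31
lower videos (preserving the ~1:5.2 imbalance of the motivating dataset at
one-tenth scale), 64×64 frames, 30–600 frames per video. A
`signal_amplitude` knob interpolates every class-dependent term toward the
class-neutral midpoint, so amplitude 0 makes the classes statistically
identical. An optional per-video, class-independent color tint
(`tint_sd`) removes whole-frame mean color as a shortcut feature.

`planted_signal_corpus` confines the class difference to a known disc
(default: centered, radius 0.35 of the half-frame): inside it the red and
green channels shift by ±signal/2 per class; outside it both classes share
one distribution. It is the ground truth for saliency-localization checks.

What passing tests on this corpus do **not** show: robustness to camera
motion blur, specular highlights, compression artifacts, lesion-level
variability, or any real anatomical texture. The synthetic classes are
separable by design; desk-scale accuracies near 1.0 reflect that design,
not clinical performance.

## Explainability

Grad-CAM weighs the final RPA stage's second-convolution activations by
the spatiotemporal mean of the target-class logit gradient, rectifies the
weighted sum, upsamples trilinearly to the segment's frame grid, and
max-normalizes. Guided backpropagation recomputes the input gradient with
ReLU backward passes suppressing negative incoming gradients. Guided
Grad-CAM multiplies the upsampled CAM with the channel-summed magnitude of
the guided gradients (the absolute value avoids sign cancellation in the
visualization); heatmaps are nonnegative with maximum 1.

**Known limitation.** Channel layer normalization has unbounded input
sensitivity wherever the channel vector is nearly constant — notably the
exactly-black corner border — because the backward pass scales by
1/sqrt(var + eps). On trained desk-scale models this concentrates guided
*gradient* magnitude in the border even though the activation-based CAM
correctly prefers the endoscopic field (in-field CAM mass ≈ 0.8 versus a
0.71 field-area fraction in our runs). Saliency-localization accuracy is
therefore validated with a *constructed* color-opponency reference model
(`xai.reference_disc_model`, not trained): its only informative pathway
detects background-nulled red-green opponency, so its Guided Grad-CAM mass
must fall in the planted disc, which the tests confirm (≈ 0.87 observed,
border mass exactly 0). Trained-model heatmaps should be read through the
CAM, not the guided-gradient factor.

## Numerical and design choices

* Frames are reals in [0, 1] (integer inputs divided by their dtype
  maximum); resizing is bilinear without aspect-ratio preservation
  (default target 224×224; desk-scale runs use the generator's native
  64×64 or 32×32 frames directly).
* Layer normalization acts over the channel axis at each position with
  learned per-channel scale/offset and eps = 1e-3 (the Keras default, and
  less prone to flat-region gradient amplification than smaller values).
* Downsampling is stride-2 max pooling over (T,H,W) with ceil semantics;
  the temporal axis is pooled only while it is ≥ 2.
* Residual skips use a 1×1×1 projection only on channel mismatch; no
  activation follows the skip addition; a single ReLU sits between the two
  conv+norm pairs.
* Weight init is variance-scaling fan-in (He) normal, seeded; per-run
  seeds derive from the master seed via `SeedSequence.spawn`, giving
  independently reproducible subset sampling, splits, weight init, segment
  sampling and inference selection.
* In the max-out branch, ties `c = s` route the max gradient to the cSE
  branch.
* Undefined metric ratios (zero denominators) are reported as 0 with a
  flag so multi-run aggregation never aborts; all-zero paired differences
  yield the degenerate t = 0, p = 1 rather than an error.
* ROC/AUC is computed with scikit-learn's trapezoidal `roc_curve`/`auc`
  on video-level positive-class probabilities, per run, then averaged.

## Desk-scale problem sizes

The test suite exercises the full pipeline at deliberately small sizes
chosen as this package's own desk-scale study conditions: the end-to-end
run trains stage widths [8, 8, 16, 16, 32] with N = 8, G = 4 on the
default 6/31 corpus for 5 runs × 15 epochs at learning rate 1e-3 (a
~60-step budget cannot move weights at the full-scale 1e-4); the ablation
compares 12 paired runs of 18 epochs on a 12/25 corpus of 32×32 frames
with N = 4, G = 4, where both arms train to saturation so the direction
check contrasts converged models. Full-scale reported numbers (accuracy
≈ 0.93 on real endoscopy video) require the real corpus and GPU-scale
training and are outside what this synthetic setup can or should
reproduce.
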