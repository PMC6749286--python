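# Methods

This note records what the package computes, the assumptions baked into it,
the default parameters, and the known limitations. Empirical numbers quoted
here are produced by the package's own tests and scripts at desk scale; no
field-data performance is claimed.

## Problem setting

Three-class semantic segmentation of nadir field imagery: every pixel is soil
(0), crop (1) or weed (2); 255 marks pixels excluded from training and
evaluation. Both networks output class probabilities on a grid 4× coarser than
the input, reflecting the assumption that plant-scale decisions do not need
single-pixel resolution and that labels near class boundaries are unreliable
anyway.

## Architectures

**Stationary U-Net** (`build_stationary`). Four encoder levels of two 3×3
convolutions each (base widths 64/128/256/512 scaled by `f_mobilenet(·, α)`),
2×2 average-pooling between levels, a two-convolution bottleneck at 1/16
resolution, and a decoder with two nearest-neighbour upscale + skip-concat
levels that stops at 1/4 resolution, followed by a pointwise classification
head and softmax. Input dimensions must be divisible by 16.

**Mobile hybrid** (`build_mobile`). A stride-2 stem convolution to width A,
then three DenseNet-Mobile blocks with pointwise transitions: a reducing block
to width B at 1/4 (kept as the skip source), a reducing block to width C at
1/8, and a non-reducing block at 1/8. The decoder upscales once, concatenates
the width-B skip, projects to width B, applies `n_residual` separable residual
units, and ends in the pointwise head. (A, B, C) is the width-multiplier
schedule applied to the base triple (16, 32, 64); stage growth rates are
`max(1, B//4)`, `max(1, C//4)`, `max(1, C//4)`. Input dimensions must be
divisible by 8.

**DenseNet-Mobile blocks** (`blocks.py`). Each of the (default 3) stages is a
depthwise 3×3 + pointwise 1×1 pair with batch norm and ReLU after the
pointwise step. The *naive* variant re-runs the depthwise filter over the full
concatenation feeding each stage; in its reducing form all stages run at full
resolution and a 2×2 average pool is applied to the concatenated output. The
*custom* variant computes each channel's depthwise response at most once
(lazily — exactly once per channel any pointwise stage consumes) and pools the
block input first when reducing. With depthwise kernels tied
(`tie_depthwise_weights`) and pointwise/BN parameters shared, the non-reducing
naive and custom blocks are numerically identical; the reducing forms differ
by design (pool-late vs pool-early) and the custom form is strictly cheaper in
multiply-accumulates for every spec on the tested grid.

Depthwise nodes carry no bias: a bias there would be absorbed by the following
pointwise layer and would break the tied-kernel equivalence between variants.

## Width schedules

`f_mobilenet(x, α) = max(1, ⌊xα⌋)` and `f_mod8(x, α) = max(8, 8⌊xα/8⌋)`.
Both are floors with a lower clamp (a "min" would make the schedule constant),
validated against exact rational arithmetic in the tests. A small fuzz (1e-9)
is added before flooring so binary representations of decimal multipliers
(e.g. 64 × 0.5) do not land just below an integer.

## Cost model

`count_macs` counts one multiply-accumulate per scalar product: output
positions × k² × C_in × C_out for convolutions, positions × k² × C × m for
depthwise, positions × C_in × C_out for pointwise; pooling, upsampling,
normalisation, activations and concatenation count zero. This is the standard
architecture-comparison convention; it ignores memory traffic and so is not a
latency predictor — the `benchmark` command reports wall-clock alongside MACs
for that reason.

## Training

The engine (`engine.py`) is a from-scratch NumPy implementation: im2col
convolutions, TensorFlow-style "same" padding (stride 2 pads
bottom/right-heavy), batch norm with running statistics (momentum 0.9, epsilon
1e-5), softmax, and Adam (default learning rate 1e-3). Gradients of every
operator are verified against float64 central differences in the test suite.

Label preparation: ground-truth masks are majority-vote downsampled 4× (ties
and all-ignore cells become 255), and pixels within a Chebyshev radius
(default 1) of a different class are set to ignore (`exclude_borders`),
reflecting the assumption that hand or synthetic labels are least reliable at
plant boundaries. Augmentation jitters brightness and saturation uniformly in
[0.7, 1.3] and applies horizontal/vertical flips jointly to image and mask.

Hard-label training minimises cross-entropy over non-ignore pixels.
Distillation minimises cross-entropy against the teacher's full probability
maps (temperature 1, every output pixel weighted equally); soft labels must be
valid per-pixel distributions. The gradient is seeded at the logits as
(p − t)·w/n, the exact softmax + cross-entropy derivative.

## Ensemble teacher

`EnsembleTeacher` averages (or takes the renormalised per-class median of)
member probability maps. `ensemble_stability` reports the Dice error between
the first-half and second-half sub-ensembles' hard predictions — a measure of
whether the ensemble is large enough that its output has stopped depending on
the particular member draw.

## Synthetic field generator

`generate_field` emulates: brown soil with low-frequency value noise and fine
grain; crop plants as rosettes of 5–9 elliptical leaves (hue ≈ 120°) centred
on a vertical row line with Gaussian jitter; weeds as smaller irregular blobs
(hue shifted by `hue_offset_deg`, default 15°, toward yellow-green) scattered
uniformly; optional harsh diagonal lighting (×1.6 bright side, ×0.5 shadow
side, probability `shadow_prob` = 0.3). Plant pixels are guaranteed
green-dominant. Image *i* of a dataset derives from seed sequence
`(seed, i)`, so the JSON manifest reproduces a dataset bit-for-bit; an
`overlap_stride` mode windows one tall strip to emulate overlapping video
frames.

It deliberately does **not** emulate: perspective or lens distortion, plant
occlusion hierarchies, species variety, soil residue/stones, motion blur,
specular highlights, or realistic illumination colour shifts. Results on these
images say nothing quantitative about real fields; the generator exists so
that pipeline behaviour (shapes, losses, orderings) is testable with exact
ground truth.

## Desk-scale study sizes

The studies in `tests/test_acceptance.py` use 48×64 images, 24 training + 10
test fields, 5 ensemble members (stationary at base widths 8/16/32/64, 30
epochs), and mobile students at α = 1.0 trained for 60 epochs. These sizes are
this package's own choice, picked so the full suite runs in minutes on one
CPU; they are not taken from any external study. The two stochastic claims are
asserted as orderings under fixed seeds only: ensemble < average single
member, and distilled ≤ directly trained, both in ground-truth Dice error on
held-out fields.

## Metrics

* `e_dice`: 100 − mean over images and classes of the Dice score (percent).
  A class absent from both prediction and label contributes a Dice of 1 by
  default (`absent_class="one"`); `"skip"` drops the term instead.
* `r_weed`, `p_weed`: weed recall/precision pooled over all pixels of all
  images (per-image averaging available via `per_image=True`).
* `m_crop_as_weed`: fraction of true crop pixels predicted weed.
* Undefined ratios (zero denominator) are returned as NaN, never silently as
  0 or 100. Ignore pixels are excluded from every count.

## Known limitations and open choices

* Single-threaded NumPy training is orders of magnitude slower than a GPU
  framework; the stationary model at full width is only practical for
  inference-scale checks here.
* Batch-norm running statistics converge slowly at desk scale; evaluation-mode
  behaviour shortly after initialisation can lag training-mode loss.
* The median combiner leaves the probability simplex before renormalisation;
  renormalising is a choice, not the only option (e.g. softmax re-projection).
* Distillation uses temperature 1 and equal pixel weights; temperature
  scaling and boundary-weighted distillation are natural extensions.
* The residual tail of the mobile network (`n_residual`, default 2) and the
  growth-rate rule (`max(1, width//4)`) are fixed conventions; neither was
  tuned.
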