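# Methods

`cpcnn` implements a cascaded-progressive convolutional network (C-PCNN)
for binary detection of meniscus injury in sagittal knee MR slices, with
weakly-supervised lesion localization. This note describes the model, the
synthetic phantoms it is validated on, the numerical choices, and what the
bundled experiments do and do not demonstrate.

## The model

A case enters as a three-level resolution pyramid of the same 2:1-cropped
grayscale slice (nominal 640×320, 1280×640, 2560×1280). Three
ResNet50-style tiers process the levels:

| tier      | input  | layers                                  |
|-----------|--------|-----------------------------------------|
| primary   | low    | conv_1, block_1–block_4, fc              |
| secondary | mid    | conv_1, block_1, block_2                 |
| tertiary  | high   | conv_1, conv_2, block_1–block_4, fc      |

`conv_1` is a 7×7/stride-2 convolution (64 ch) plus 3×3/stride-2 max pool;
`block_k` stacks bottleneck units with channel triplets (64,64,256),
(128,128,512), (256,256,1024), (512,512,2048), repeated (3,4,6,3) times,
blocks 2–4 downsampling by stride 2 in their first unit. The tertiary
tier's extra `conv_2` (3×3, 64 ch, stride 2) halves its maps once more so
its `block_2` tap exactly matches the secondary `block_2` tap
(160×80×512 at nominal size), making cross-tier fusion a plain sum.

Information cascades coarse→fine:

1. **Primary** classifies the low-resolution image. Grad-CAM on a hook
   inside `block_3` turns it into a lesion localizer: channel weights are
   the spatial means of ∂(injury logit)/∂(feature map), the map is the
   ReLU of the weighted channel sum, normalized to [0,1] and bilinearly
   upsampled to the low-level image size. The localization is *weakly
   supervised*: pixel masks are never used for training.
2. **Secondary** runs to `block_1`; the primary `block_1` features are
   bilinearly upsampled 2× and added; `block_2` follows.
3. **Tertiary** runs through `conv_1`/`conv_2`/`block_1`/`block_2`; the
   secondary and tertiary `block_2` taps are summed, and the **lesion
   attention module** (LAM) re-weights the fused features before
   `block_3`, `block_4` and the final two-class head, which produces the
   diagnosis.

### Lesion attention module

The LAM combines the secondary tap (low), the fused tap (high), and the
localization map:

* *Feature attention*: 1×1 bias-free linear transforms bring both feature
  inputs to the high input's channel width; they are summed, reduced to
  one channel by a 1×1 convolution, and softmaxed over spatial positions.
  The softmax is rescaled by H·W so the mean weight is 1 — without this
  the product would shrink with map size and uniform attention would not
  be the identity.
* *Location attention*: the [0,1] map resized to the feature size, used
  as `1 + map`. Healthy-tissue features keep weight 1 and lesion evidence
  amplifies up to 2×. Multiplying by the raw map would null every feature
  of a healthy knee and destroy classification of normal cases; the
  shifted form realizes "amplify the lesion area" without suppression.
  How exactly the published module combines the two maps is not
  operationalized anywhere we could find; this composition
  (`transform(high) ⊙ feature_attention ⊙ location_attention`) is our
  design choice.

The hook layer is the post-BN output of the third convolution of the
first bottleneck unit of `block_3` ("block_3.0.conv3"); which of the
repeated units carries the hook is ambiguous in the source description,
so the name is configurable. The class differentiated for the map is the
injury class (1) during training, the predicted class at inference.

## Training

Two stages (`cascade.train`):

1. **Stage 1** trains the primary tier alone with cross-entropy on image
   labels.
2. **Stage 2** freezes the primary (its `block_1` features and
   localization maps are precomputed once per case, since they no longer
   change) and trains secondary + tertiary + LAM with cross-entropy on
   the final head. Training *through* the Grad-CAM map would require
   second-order gradients; the map enters stage 2 as a constant per-case
   input. The frozen primary's cross-entropy is reported in the log with
   weight λ_primary but contributes no gradient.

Optimizer: SGD, momentum 0.9, cosine-decayed learning rate, batch 8,
weight decay 0. Defaults: lr 0.01, 50+50 epochs at full scale. The tiny
preset uses lr 0.05 for stage 1 but **0.01 for stage 2**
(`cascade_learning_rate`): the deeper randomly-initialized cascade head
oscillates at 0.05 while the shallow primary benefits from the higher
rate. NaN loss aborts with a diagnostic. All randomness (initialization,
shuffling, phantom rendering) derives from explicit integer seeds; two
runs with the same config are bit-identical.

The decision threshold is 0.5 with ties classified injured.

## The tiny preset

Full-scale tiers at 2560×1280 are far beyond a single CPU. The `tiny`
preset — width multiplier 0.25, one bottleneck unit per block, 160×80
base resolution (pyramid up to 640×320) — preserves every structural
property (tap arithmetic, fusion-size guarantee, Grad-CAM hook, LAM) at
about 1/4000 of the compute. All bundled training runs use it; one
200-case training run takes roughly four minutes on one core.

## Compute engine

The tiers run on a small reverse-mode autodiff engine written for this
package (`cpcnn._tensor`, `cpcnn.nn`): a tape-based `Tensor` over float32
NumPy arrays with convolution, batch normalization, max pooling,
bilinear resizing, global average pooling and softmax losses.
Activations are channels-last (N,H,W,C) and convolutions are computed as
sums of per-offset GEMMs over shifted row-contiguous slices (stride > 1
via phase decomposition), which keeps a single core near BLAS speed.
`cpcnn._malloc` raises glibc's malloc thresholds so large temporaries are
reused from the heap instead of round-tripping pages through the kernel —
about 6× on allocation-bound steps. The backward pass of every operation
is verified against finite differences, and the full tape against a
double-precision independent reimplementation of a network tail
(agreement ~1e-6 relative).

Batch statistics use biased variance; running statistics use momentum
0.1; eps 1e-5. Max-pool gradient ties route to the first window position
in raster order (argmax convention). The in-network bilinear resize uses
half-pixel centers with edge clamping and is exactly linear, so its
transpose is its backward; preprocessing-side resampling
(`imageio.build_pyramid`) instead uses `skimage.transform.resize` with
anti-aliasing on downsampling.

## Synthetic phantoms

No public dataset of the source cohort exists, so `cpcnn.phantoms`
generates knee-like scenes with known ground truth: a bright noisy
background (mean 0.60, Gaussian σ 0.05, clipped to [0,1]), one or two
dark triangular wedges (mean 0.20) mimicking the meniscal horns in a
sagittal view ("bow-tie" when both are present, vertex jitter ±4% of
image height), and — in injured cases — a thin bright streak (mean 0.95,
2 px wide at base resolution) clipped to the host wedge, emulating the
high-signal line of a tear. Geometry is rendered from signed-distance
fields independently at each pyramid level with a one-pixel anti-alias
band, so higher levels are crisp renderings of the same scene, not
upsampled copies. Labels are Bernoulli(0.5) by default; the lesion mask
and host horn are exported per case. Each case draws from a counter-based
stream keyed by (seed, case index).

The phantoms deliberately omit MR physics (bias fields, coil artifacts,
anatomy beyond the menisci, 3-D continuity). Passing the recovery
experiments therefore shows the *pipeline* — cascade wiring, weak
supervision, localization, attention, evaluation protocol — works end to
end on images with the stated contrast structure; it says nothing about
clinical performance on hospital data.

## Evaluation protocol

`evaluate.make_folds` shuffles (seeded), stratifies by label, and deals
k=5 folds whose sizes differ by at most one (1396 cases → 280+4×279);
each fold is the test set in turn. Stratification is our choice — the
source protocol doesn't state it — because it matches the near-balanced
cohort and avoids degenerate single-class folds at small n. Metrics from
tp/tn/fp/fn: accuracy, precision, recall, specificity, F1; a metric with
a zero denominator is reported as undefined and flagged, never coerced
to 0, and fold means average only defined values. AUC is the tie-aware
(half-credit) threshold-sweep trapezoid, equal to the Mann–Whitney
statistic. Display rounding is 4 decimals, half-up.

`evaluate.localization_score` counts a hit when the upsampled map's
argmax (raster order on ties) falls inside the lesion mask dilated by a
disk of radius 9 px.

## Bundled experiments and their scale

* **Phantom recovery** (acceptance): tiny-preset cascade trained on 200
  phantoms (160×80 base), evaluated on 100 fresh ones; three training
  seeds, median reported. Observed: held-out AUC ≈ 1.0 for every seed;
  localization hit rates vary more (roughly 0.29–1.0 across seeds)
  because the native Grad-CAM map at this scale is only 10×5 cells —
  the correct horn is essentially always identified, but for some seeds
  the peak lands one native cell below the thin streak. The median
  comfortably exceeds the 0.70 hit-rate bound.
* **Cross-validated recovery**: 5-fold rotation on 100 phantoms at a
  further reduced 96×48 base, mean AUC ≥ 0.85 asserted.
* Problem sizes were chosen so the full test suite and the acceptance
  script each run in well under half an hour on one CPU core.

## Known limitations

* Single 2-D slice per case; no multi-slice or 3-D aggregation.
* Tear-direction subtyping is out of scope.
* The "improved" Grad-CAM variant alluded to in the source (extra
  conv+GAP+softmax appended to the network) is not fully specified; we
  implement standard Grad-CAM at the stated hook.
* An optional auxiliary secondary-tier classification head exists
  (`aux_secondary_head`) but is disabled by default and never enters the
  loss; whether the secondary tier had its own supervised output in the
  original design is unclear.
* Grad-CAM localization precision is bounded by the hook's native
  resolution; at desk scale that is coarse relative to a 2-px streak.
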