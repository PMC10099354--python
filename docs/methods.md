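# Methods

## Problem and pipeline

Microaneurysms (MAs) are near-circular dark-red lesions of at most ~50 px
diameter in multi-megapixel color fundus photographs (reference device
resolution 2124 × 2056 px). Down-scaling a whole frame to a network-sized
input would shrink an MA by a factor of ~36 in area and merge it with the
background, so the pipeline keeps lesions at native scale and instead cuts
the frame into overlapping square patches:

* **Grid.** Window `w` (default 576 px), overlap fraction `o` (default
  0.30), stride `s = floor(w·(1−o))` (403 px at the defaults). Origins
  advance `0, s, 2s, …` per axis; if the last regular window does not
  reach the image edge, one extra window anchored flush at
  `axis_size − w` is appended. Coordinates are 0-based, row-major,
  windows half-open. This guarantees full coverage without padding, at
  the price of extra overlap in the last row/column.
* **Black-patch rule.** At training time, windows in which *every* pixel
  of every channel is ≤ `black_tol` (default 0) are discarded — they lie
  outside the camera's circular field of view and contain no signal. At
  inference nothing is discarded: the reconstruction divides by the
  per-pixel overlap count, which must be ≥ 1 everywhere.
* **Reconstruction.** Each predicted patch is added onto a probability
  canvas at its crop origin; a parallel integer canvas counts covering
  windows. The final map is `prob_sum / count` — the mean of the
  overlapping predictions — binarized by a *strict* threshold
  (`prob > 0.5`; a pixel at exactly 0.5 is background). Accumulation is
  commutative, so patch order is irrelevant.

## Architectures

All three networks map an RGB patch (values scaled to [0, 1]) to a
two-channel 1×1-convolution head under a channelwise softmax; the
foreground channel is the probability map. Output spatial size always
equals input size.

* **U-Net** (reference: input 576, depth 5): encoder stages of two 3×3
  conv + BatchNorm + ReLU with widths 16/32/64/128/256 and 2×2 max-pool;
  a two-conv 512-channel bottleneck at 18×18; a mirrored decoder with
  nearest-neighbour 2× up-sampling and skip concatenation. 7,865,426
  trainable parameters. Only the bottleneck shape (18×18×512) and the
  parameter floor (> 7.7 M) are fixed constraints; the width schedule here
  is a documented choice satisfying both, not a claim of exact fidelity.
* **ResNet34-UNet**: a standard ResNet34 convolutional body (7×7/2 stem,
  3×3/2 max-pool, residual stages 64/128/256/512 with identity skips and
  1×1 projections on the strided blocks) as encoder — its deepest feature
  at input 576 is 18×18×512 — and a five-block decoder of widths
  256/128/64/32/16 with an additive attention gate on every skip and the
  raw input image concatenated before the final block. 24,570,364
  trainable parameters (> 21.6 M). The attention gate follows the
  standard additive formulation (1×1 maps of skip and gating signal,
  ReLU, 1×1 single-channel sigmoid, pointwise scaling); the source
  description names the module but gives no equations. ImageNet
  pre-training of the encoder is intentionally optional and off by
  default so the package builds fully offline; requesting it without
  weights is an error.
* **U-Net++** (reference: depth 4, widths 32/64/128/256/512): nested
  dense skips — node `X(i,j)` consumes the up-sampled `X(i+1, j−1)`
  concatenated with all `X(i, 0…j−1)`; every node is a two-conv block.
  Deep supervision (off by default) attaches 1×1 heads to `X(0, 1…4)`
  and averages their logits. 9,159,714 parameters at the reference
  configuration.

`base_width` scales every width proportionally, and `depth` (U-Net and
U-Net++) sets the number of down-samplings, so desk-scale variants (input
64, base width 8) build and run in well under a second on one CPU.
Parameter counts depend only on the configuration. One scaling caveat: the
ResNet34-UNet's last two decoder widths are floored at `min(8, base_width)`
channels — the reference schedule is unchanged, but without the floor a
base width of 8 leaves 4- and 2-channel stages at full resolution, too
little capacity to reconstruct small lesions (observed as a collapsed
benchmark member).

## The numpy CNN engine

No GPU framework is used: `maseg.nn` is a small reverse-mode autodiff
engine on float32 numpy arrays (NCHW) with exactly the ops the
architectures need — conv2d, batch norm, max-pool, nearest up-sample,
concat, ReLU/sigmoid, attention gating, fused softmax cross-entropy, and
Adam. Convolution is computed as a single GEMM over all padded positions
with the kernel offsets unrolled, summed through strided views; this is
gather-free and fast in numpy's memory model. Gradients are verified
against brute-force adjoints and finite differences in the test suite.
After `backward()` the tape is dismantled explicitly because the backward
closures hold reference cycles that would otherwise pin every intermediate
activation until garbage collection. Weight initialization is seeded
Kaiming-normal; training on one device is bit-reproducible for a fixed
seed.

## Training protocol

Patches are paired with ground-truth crops cut from the full-image mask at
identical origins. The patch set is shuffled with a seeded permutation and
split 70/10/20 (train/validation/test); sizes are `floor(n·frac)` with the
remainder to test, so 1,000 patches give exactly 700/100/200. The loss is
two-class cross-entropy under the softmax head — equivalent to binary
cross-entropy on the foreground probability — optimized with Adam. After
every epoch the micro-averaged validation Dice at threshold 0.5 is
measured and the best epoch's weights are kept. Because MA pixels are
~1–3% of a patch, each epoch draws lesion-bearing and lesion-free patches
in comparable numbers (`balance_positives`); this standard imbalance
remedy only changes the sampling distribution, not the loss.

The ensemble averages the three members' probability maps pixelwise
*before* thresholding, consistent with the averaging-then-threshold
reconstruction; majority voting is available behind a flag for comparison.
The mean is bounded by the member extrema at every pixel, so the ensemble
cannot leave [0, 1].

## Synthetic data

The generator emulates the *geometry* of annotated fundus data, not its
photographic appearance: a circular illuminated field of view (radius 0.49
of the short side) on a black frame; a reddish background with smoothed
Gaussian texture and a radial illumination falloff; vessel-like curves as
smoothed random walks stamped with tapering disc thickness and darkened
~42%; and `n_mas` non-overlapping disc blobs with a soft Gaussian edge,
darkened up to 65% at centre. Each blob's exact disc support goes into the
ground-truth mask; blob centres keep a margin of one diameter from the
field-of-view rim and a 2 px mutual gap so every blob is a separate
connected component. Placement is rejection-sampled with a bounded retry
budget and fails loudly when the requested count cannot fit. All
randomness flows from one PCG64 generator per sample; datasets draw
per-image seeds from a spawned SeedSequence.

Defaults: 640 × 640 px, 10 blobs of 5–50 px diameter, 8 vessels,
illumination amplitude 0.3, noise σ 3. The full-frame 2124 × 2056 size is
supported but not default. What passing tests on this data shows: the
tiling/reconstruction algebra is exact, the networks can learn and
localize small dark blobs, and the ensemble plumbing is correct. What it
does not show: performance on real fundus photographs, robustness to
acquisition noise, or anything about clinical scores — real MAs are far
subtler than these synthetic blobs.

## Desk-scale benchmark

`maseg.benchmark.run_desk_benchmark` fixes the study conditions used by
the acceptance tests: 30 synthetic images of 320 × 320 px (10 blobs of
5–20 px — proportionate to the smaller canvas and within the ≤ 50 px
clinical bound — and 5 vessels), window 64 at 30% overlap (≈ 1,470
patches, split 1,029/147/294), members at base width 8 (U-Net and U-Net++
at depth 3), and one shared hyper-parameter set — Adam, lr 5 × 10⁻³,
batch 16, 6 epochs — mirroring the same-hyper-parameters protocol of the
original experiment at roughly 1/50 of its scale. Reported scores are
micro-averaged Dice (pooled TP/FP/FN over held-out test patches, threshold
0.5); micro-averaging avoids crediting the all-empty agreement that a
per-patch mean would count as 1.0. The learning rate and batch size were
chosen for convergence speed on one CPU; the epoch count is what the
slowest-converging member (ResNet34-UNet, whose stem discards ¾ of the
spatial resolution before the first residual stage) needs to push lesion
probabilities past the 0.5 threshold.

## Numerical and degenerate-case choices

* Metrics are pixelwise over whole images; no per-lesion matching. When
  both masks are empty, IoU and Dice are defined as 1.0 (agreement on
  absence) and flagged `degenerate`; per-image scores are averaged
  unweighted across images.
* Thresholding is strictly `>`, so ties at exactly 0.5 go to background.
* `finalize_map` refuses canvases with uncovered pixels rather than
  dividing by zero; `accumulate` validates probability range and bounds.
* Mask files follow the annotation convention: lesion = black (0),
  background = white (255); reading binarizes at the intensity midpoint
  and warns when a file does not look binary.
* Checkpoints are numpy `.npz` archives with a JSON sidecar carrying the
  full architecture configuration, so parameter counts are auditable
  without loading weights.

## Known limitations

Pure-numpy training is ~100× slower than a GPU framework, so full-scale
(576 px, reference-width) training is impractical here; the package trains
scaled-down configurations and treats the full-size builders as
configuration/counting artifacts plus slow-but-correct predictors. The
synthetic generator's blobs are more conspicuous than clinical MAs, the
µm-to-pixel scale of real devices is not modelled, and other diabetic
retinopathy signs (hemorrhages, exudates) are out of scope.
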