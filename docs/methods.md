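# Methods

`spinemark` implements a two-stage landmark detector for lateral lumbar
radiographs together with a phantom generator that makes the whole chain
testable without clinical data.

## Problem and model

A lateral lumbar study is annotated with 6 vertebra centers (L1–L5 and the
first sacral vertebra S1) and 22 corner landmarks: the four end-plate
corners of each lumbar body (top-left `Lt`, top-right `Rt`, bottom-left
`Lb`, bottom-right `Rb`) and the two endpoints of the S1 upper end plate.
The S1 lower plate is not annotated; it is rarely legible on radiographs.

**Stage one (centers).** The preprocessed 512×512 image is mapped to six
64×64 confidence maps, one per center, with Gaussian ground truth

    C_i(x) = exp(−‖x − c_i‖² / 2σ²),   σ = ½ · (vertical extent of L5),

σ expressed in heatmap pixels and recomputed per image.  The network is a
U-shaped encoder–decoder with pre-activation blocks (instance norm → ReLU
→ conv).  Two 13×13 convolutions sit at the bottleneck: at the heatmap
scale neighboring centers are only ≈7 px apart, so widened kernels let the
network infer an invisible center from its neighbors.  An intermediate
branch pre-predicts the L5 map (the brightest, most reliable body) and is
concatenated back into the trunk before the 6-channel head.  The loss is

    L = ‖Ĉ₅ − C̄₅‖² + (1/6) Σᵢ ‖Ĉᵢ − Cᵢ‖²,

both terms plain sums of squared differences.

**Decoding and repair.** Centers are per-channel argmaxes (row-major
tie-break).  The characteristic failure is a *shifted set*: the body above
L1 (T12) is taken for L1 and every channel down to some level j locks onto
the vertebra above its target.  With gaps dᵢ = ‖max(Cᵢ) − max(Cᵢ₊₁)‖₂, the
set is flagged when max(d) > 1.4 · mean(d excluding its maximum).  Repair
sums all channels, keeps only the rows within the central band of the
suspicious gap (`y ∈ [y_j + 0.4·d_max, y_{j+1} − 0.4·d_max]`, d_max the
y-distance of the flanking maxima), takes the surviving argmax as the
recovered center, drops the topmost original maximum and inserts the new
point between j and j+1.  Only this upward-shift mode is repaired; a
spurious *bottom* point is flagged but returned unrepaired with a warning,
because the insertion rule is only defined for the top case.  The 1.4 and
0.4 constants are exposed in `postprocess` as module constants.

**Cropping.** Square per-vertebra windows centered on the decoded centers,
with side 1.5× the single adjacent center gap at the ends (L1, L5), 0.75×
the sum of both gaps for L2–L4, and — because the L5–S1 distance is highly
variable — the L4–L5-derived value for S1.  Windows are cut from the
zero-padded original, resized to 256×256 and blurred.  All frames
(original, padded, 512-input, 64-heatmap, crop) are linked by invertible
pure scale+offset transforms; crop pixel 128 maps exactly onto the window
center.

**Stage two (corners).** Two M-Net-style encoder–decoders, identical
except for the head: lumbar = 4 corner confidence maps + 1 part affinity
channel; sacrum = 2 maps + 1.  Multi-scale downsampled copies of the crop
are injected at every encoder stage; the first two encoder stages use
CoordConv (two constant coordinate channels in [−1, 1] concatenated before
the convolution), which deliberately breaks translation equivariance so
the network can exploit that crops are center-aligned and corners occupy
predictable regions.  The part affinity field is a scalar indicator
raster: 1 within width/2 (default width 4 px, band convention [−w/2, w/2)
so an axis-aligned width-4 band covers exactly 4 rows) of the `LtRt` or
`LbRb` end-plate segment (both plates share one channel), teaching the
trunk the body's shape.  Corner map σ is 1/10 of the mean corner diagonal;
sacrum σ is 1/6 of the plate length.  Loss:

    L_lumbar = (1/4) Σ ‖Ĉᵢ − Cᵢ‖² + α ‖P̂ − P‖²,  α = 0.001
    L_sacrum = (1/2) Σ ‖Ĉᵢ − Cᵢ‖² + β ‖P̂ − P‖²,  β = 0.01

Training crops are built around **ground-truth** centers (with optional
translation jitter, `crop_jitter_sd` = 4 px, standing in for
center-prediction error); inference crops around **predicted** centers.
This asymmetry is deliberate and enforced by the pipeline's construction.

## Augmentation

*Random spine cutout* (RSC) zeroes a rectangle sized 60% of one randomly
chosen upper lumbar body's box (L1–L4, the bodies most often shadowed),
placed uniformly inside that box, applied with probability 0.5 per sample;
annotations are untouched.  The conventional-cutout baseline zeroes a
similar-sized rectangle anywhere in the frame.  Photometric jitter
(brightness ±20, contrast 0.85–1.15) and a similarity warp (rotation
σ = 3°, scale 0.95–1.05, translation ±15 px, reflection-padded resampling)
are applied to pixels and annotations identically.  The RSC rectangle's
*position* is uniform rather than centered — the size is the stated
contract, the placement was an open choice.

## The phantom generator

The phantom emulates the statistics the detector relies on, nothing more:
six convex quadrilateral bodies stacked top to bottom at spacing 71 px
(≈1/9 of the 640-px default height, i.e. ≈7 px at heatmap scale, jitter
σ = 3 px), body size 58×48 px (σ = 4/3 px), tilt σ = 4°, lateral/vertical
placement jitter σ = 10 px.  Interior mean intensities follow values
measured on real radiographs (L1..L5 = 137.11, 132.20, 130.83, 140.09,
163.02); S1 is not part of the measured set and is set to 170, continuing
the brighter-toward-the-sacrum trend.  Background 90, pixel noise σ = 8.
S1 is a wedge tilted ≈20° whose two annotated points are its upper-plate
endpoints.  With probability 0.35 a full-width darkening band (height 0.8×
the body, factor 0.45) crosses one of L1–L4, emulating rib/diaphragm
shadow; no quantitative occlusion statistics exist for real data, so the
rate is a free parameter chosen to make occlusion common but not dominant.

What the phantom does **not** emulate: radiographic texture, projection
geometry, pathology (fractures, transitional vertebrae), soft-tissue
gradients.  Passing tests therefore demonstrate that the *mechanisms*
(targets, losses, repair, coordinate bookkeeping, training dynamics) are
wired correctly — not clinical-grade accuracy on real radiographs.

## Numerical choices

* Gaussian targets are centered on the annotation rounded to the nearest
  pixel so every ground-truth channel peaks at exactly 1 (the decode
  contract); maps are not renormalized.
* Argmax decode uses row-major first occurrence on ties; a constant
  channel falls back to the centroid with a warning.
* Padding anchors content top-left so original→input is a pure scale with
  zero offset; the heatmap scale is exactly 8 with no half-pixel shift.
* The tensor framework (`spinemark.nn`) is a small reverse-mode tape over
  numpy: convolution is decomposed into per-kernel-offset BLAS matmuls on
  shifted NHWC views (faster on CPU than an im2col copy at these channel
  counts); gradients are validated against finite differences in the test
  suite.  Weights use He initialization from a seeded generator; training
  is Adam with linear learning-rate decay and patience-based early
  stopping, restoring best-validation weights.
* Degenerate predictions (coincident neighbor center y's) would make the
  crop-side rule produce a zero side; inference substitutes a floor of
  0.25× the mean positive gap so a full result is always produced.

## Scaled-down experiment sizes

Full-protocol training (hundreds of epochs, batch 16/32 at learning rate
1e-4) is the library default, but the shipped experiments use problem
sizes chosen for a single CPU: 200 training phantoms without occlusion and
with fixed spacing, a center net with 8 base channels trained 20 epochs
(Adam, lr 1e-2, batch 2), landmark nets with 4 base channels and 3 encoder
stages trained 10 epochs (lr 1e-2, batch 2) on 250 ground-truth-centered crops, and
50 held-out phantoms for evaluation.  Augmentation is disabled in these
runs: at this epoch budget cutout slows convergence more than it helps,
and the easy-phantom conditions contain no occlusion to be robust against.
Under these conditions the center stage reaches a few pixels of mean error
at the 512 scale with a low crop-outlier ratio, and the lumbar stage
reaches a relative distance error well under the 20% vertebra-outlier
threshold; `scripts/acceptance.py` recomputes all of these from scratch.

## Known limitations

* Only the upward-shift center failure is repaired, matching the defined
  procedure; multi-missing-center and bottom-intruder cases are flagged
  only.
* The phantom's regular geometry makes CoordConv unusually effective;
  real anatomy (scoliosis, transitional vertebrae) would shift the balance
  between location priors and appearance cues.
* RD normalizers (`h`, `v`) are read from the *same* vertebra's edges
  incident to the ground-truth corner; reading them from neighboring
  vertebrae is a defensible alternative and would change RD values by
  roughly the edge-length ratio.
* `σ` for the center maps is computed per image from L5's extent; a
  train-set average is a possible alternative reading and would slightly
  smooth target sharpness across images.
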