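# Methods

## Segmentation network

The segmenter is a nested encoder/decoder in the U-Net++ family with the
"fast" substitutions: no pooling anywhere — the encoder halves the
spatial resolution with 5x5 convolutions at stride 2 (leaky ReLU, slope
0.2, then batch normalisation) — and all upsampling is done by 5x5
transposed convolutions at stride 2. With depth 5 the encoder produces
feature maps X[i][0] at 1/2 ... 1/32 of the input resolution.

Between encoder and output sits a triangular grid of nested nodes
X[i][j] (i + j < depth). Every node up-convolves the deeper node
X[i+1][j-1] to level-i resolution (transposed conv, ReLU, batch norm)
and then fuses it with its same-level inputs — the encoder feature
X[i][0], plus the previous node X[i][j-1] when j >= 2 — by channel
concatenation followed by a learned 1x1 convolution. The source
description fixes the node inputs and the up-conv/ReLU/batch-norm
composition but not the fusion operator; concatenation + 1x1 convolution
was chosen so the fusion weights are learned rather than fixed (an
additive merge is the cheaper alternative and was rejected for that
reason). With deep supervision the outputs of all top-level nodes
X[0][1..depth-1] are concatenated before the final transposed
convolution; a 1x1 convolution and a sigmoid produce the single-channel
probability map at the input resolution. The plain (non-nested) variant
keeps the classic shape: each decoder stage is a transposed convolution,
ReLU, dropout (rate 0.5) and batch norm, concatenated with the
same-level encoder feature; nested nodes carry no dropout, matching
their stated composition.

Defaults: depth 5, kernel 5, filter widths **(14, 28, 56, 112, 224)**.
The widths are the one architectural quantity the source does not print;
they were calibrated once against its only quantitative architectural
claim — a total of ~1.5e10 FLOPs at 320x480x1 under the per-layer count
`FLOPs = 2 K^2 C_in C_out N` — and then frozen. With N read as the
number of *output* spatial positions of each layer (the standard
convention; the source's wording is ambiguous) the default total is
1.472e10, within 2% of the printed value. `count_flops` is pure
arithmetic over the same declarative layer plan the builder consumes, so
the two cannot drift apart.

Training: dice loss (the selection metric is DSC, so the loss matches;
the source names no loss), Adam with learning rate 1e-4 — the printed
"10e-4" is read as the conventional 1e-4 — batch size 32, and weight
initialisation from N(0, 0.02). "Maximum number of iteration steps 47"
is treated as 47 passes over the training split; both are configurable.
The best-validation-DSC weights are checkpointed and restored. All
randomness (init, shuffling, dropout) flows through one seeded
generator; with a fixed seed, builds and training runs are bit
reproducible.

The engine underneath is a small NumPy implementation: im2col + BLAS
matmul for the strided convolution, and the transposed convolution
implemented as its exact adjoint (verified to inner-product identity in
the tests, alongside naive-loop forward oracles and finite-difference
gradient checks). Inference post-processing binarises at 0.5, keeps the
largest 8-connected component and fills interior holes — a conservative
reading of the single smooth contours the method is expected to produce;
no rule is stated in the source.

## Measurement chains

Coordinates are (row, col) with row increasing downward; angles are
measured from the horizontal, positive counterclockwise on screen.
Distances are between pixel centres and spacing is isotropic (mm/px).

**Sagittal.** KL is the farthest pair among capsule contour pixels
(pixels with a background 4-neighbour), found by exhaustive O(n^2)
search — contours are a few hundred pixels, so no rotating-calipers
shortcut is needed and the result is exactly checkable against a
brute-force oracle. The mask is rotated by the KL-axis angle (canvas
enlarged, nearest-neighbour for masks, bilinear for images, with an
invertible affine record). KT is the vertical caliper from the topmost
pixel to the bottommost pixel *in the same column*; the topmost raster
row of a horizontal kidney is a flat run, and the caliper sits at the
run's median column — the run's edge would shorten the chord by up to
~3 px, which is a rasterisation artefact rather than anatomy.
Parenchymal thickness takes the per-column topmost capsule contour
("upper contour"), finds each point's nearest sinus-contour point, and
returns the pair with the largest such distance (max–min). The literal
"farthest points between the two contours" (max–max) would measure
capsule-pole to opposite-sinus-pole — not a thickness — so max–min is
the default and max–max is available behind `strategy="maxmax"`.

**Axial.** Orientation comes from PCA on the foreground pixel
coordinates; the dominant eigenvector's angle is mapped to (-90, 90],
with a degeneracy convention (angle 0, warning) when the variance ratio
is below 1.05. After rotation to horizontal, the hilum shows as a
concavity: a vertical line through it crosses the boundary >= 4 times
(crossings are counted as mask-run starts and ends in a column, which is
robust where a whole column of boundary pixels would miscount). The
hilum side is the side whose crossing signature appears closest to its
edge, overridable by flag. Axial KT runs from the middle of the first
>= 4-crossing column (scanning inward from the hilum side; "middle" =
mean of the crossing rows) to the extreme pixel on the opposite side
(ties broken by median row). KW separates the contour into its upper and
lower parts and returns the largest nearest-point distance from upper to
lower. The parts are the per-column top/bottom contour envelopes rather
than the traced ring cut at the left/rightmost points: ring-cutting
places notch-wall pixels into one of the chains and inflates the width
by tens of pixels on notched shapes, while the envelopes keep the
caliper on the outer silhouette. All landmarks are mapped back to the
original frame through the recorded affine; the one-sentence conflict in
the source — the text calls the upper/lower nearest-pair maximum the
*thickness* while its figure labels it KW — is resolved in favour of KW,
since the hilum caliper already provides the axial thickness.

**Volume.** KL and KT from the sagittal view and KW from the axial view
enter `V = KL x KW x KT x 0.523` (mm), divided by 1000 to report ml.

## Phantom generator

The phantom emulates the *geometry* the pipeline depends on, not
ultrasound physics. The sagittal capsule is an ellipse (optionally with
a low-order radial "bean" perturbation, default off) with the sinus a
concentric copy scaled by `sinus_scale`; the axial capsule is an ellipse
with a hilum notch — a disc of radius `hilum_notch_depth x semi_minor`
subtracted at the medial vertex — which produces the >= 4-crossing
signature the axial chain keys on. Images are a smooth three-level
tissue template (background 0.15, parenchyma ~0.45–0.5, sinus/core
0.7–0.8, Gaussian-blurred) multiplied by a speckle-like field: a
low-pass-filtered standard normal scaled by `speckle_sigma` (default
0.3, grain 2 px), clipped positive. With `speckle_sigma = 0` the image
is exactly the noiseless template. The exact speckle law is a modelling
choice; nothing downstream depends on it.

Ground truth is computed from the *continuous* generating curves,
independent of rasterisation: KL as the longest boundary chord (2a for
an ellipse), sagittal KT as the vertical extent after the KL axis is
horizontal (2b), parenchymal thickness as the continuum max–min from the
upper capsule boundary to the sinus boundary (a(1 - sinus_scale) at the
pole for concentric ellipses), axial KT as the span from the column
where the notch prongs meet (root of the ellipse/disc half-height
equation) to the opposite vertex, and axial KW as the continuum
upper-to-lower max-of-nearest between the boundary envelopes (2b for
elongated shapes; slightly less when the notch brings mid-height
boundary closer to the top centre). Volume combines the sagittal KL/KT
truth with the axial KW truth.

Default sampling ranges emulate adult kidneys at the stated calibration:
spacing uniform in [0.23, 0.36] mm/px, sagittal semi-major 120–172 px in
a 320x480 frame (i.e. KL roughly 70–120 mm), aspect 0.36–0.5, sinus
scale 0.45–0.6, rotation ±25°, axial semi-major 95–130 px with aspect
0.42–0.52 and notch depth 0.3–0.5; smaller frames scale the axes
proportionally. The axial aspect ceiling is deliberate: for rounder
cross-sections the continuum width partially hinges on the 1-px-thin
ellipse tips, which nearest-neighbour rotation cannot preserve, so the
analytic truth would no longer be recoverable from the raster mask to
pixel tolerance — the range keeps the measured quantity determined by
raster-robust geometry. What passing phantom tests shows is that the
*geometry* of every caliper is correct to ~2 px; it says nothing about
segmentation quality on real speckle, shadowing, or pathological
anatomy (cysts, tumours), which the generator does not model.

## Evaluation

Overlap metrics are standard (DSC, Jaccard; both-empty defined as 1.0
with a warning so a blank fold cannot crash a sweep). Surface metrics
are contour-to-contour nearest-neighbour distances: MAD averages the two
directed mean distances (the common symmetrisation; the cited definition
is not spelled out in the source), HD is the symmetric Hausdorff
maximum, SSD pools all nearest distances from both directions. The
biomarker agreement evaluator is explicitly a reinterpretation: the
binarisation behind the source's accuracy/AUC/sensitivity table is never
specified, so here a case "agrees" when its relative error is within a
configurable tolerance (default 10%), reference labels default to
all-positive and can be supplied per case, and AUC (score `1 - relative
error`) is only defined when both label classes occur.

## Scaled-down study sizes

Desk-scale checks use the full pipeline at reduced problem sizes chosen
as the package's own test conditions: oracle-equivalence masks at
160x240, parameter recovery on 50 sagittal + 50 axial full-size
(320x480) phantoms, and training at 64x64 with depth 4 and widths
(8, 16, 32, 64) on 200 phantom pairs for 30 epochs (learning rate 1e-3
for the small problem), which reaches validation DSC >= 0.9 averaged
over three seeds.

## Known limitations

- The phantom is a geometric stand-in; no attenuation, shadowing,
  refraction or probe artefacts, and no pathological shapes.
- The sinus is segmented by a second independently trained
  single-structure model (whether the original used one model or two is
  unstated); a two-channel head would be a natural extension.
- Width from the sagittal view (used in one of the source's comparisons)
  is not implementable from the description and is out of scope.
- The agreement evaluator cannot reproduce the source's CT-agreement
  table, whose construction is undocumented; it is provided as a
  clearly-labelled, configurable analogue.
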