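# renalus

Automated kidney morphometry from 2-D ultrasound. The package segments
the kidney capsule and sinus with a nested fully-convolutional network
(Fast-Unet++ style) and turns the masks into the five biomarkers that
drive clinical assessment of renal size: kidney length (KL), width (KW),
thickness (KT), parenchymal thickness, and the ellipsoid volume

```
V [ml] = KL x KW x KT x 0.523 / 1000      (lengths in mm)
```

where 0.523 ~ pi/6 is the prolate-ellipsoid coefficient.

It is aimed at medical-image-analysis researchers who want a fully
inspectable, desk-scale implementation of the whole chain — network,
geometric post-processing, and evaluation — with a synthetic phantom
generator supplying analytically known ground truth, so every stage can
be validated without access to clinical data.

## What is inside

- **`renalus.network`** — Fast-Unet++ (nested, deeply supervised) and its
  plain Fast-Unet baseline: 5x5 convolutions with stride 2 instead of
  pooling in the encoder (leaky ReLU 0.2, batch norm), 5x5 transposed
  convolutions for decoding, a triangular grid of nested fusion nodes,
  dice loss, Adam (batch 32, learning rate 1e-4, weights ~ N(0, 0.02)),
  plus analytic per-layer FLOPs accounting `2 K^2 C_in C_out N`. The
  engine is a compact, fully tested NumPy implementation (im2col
  convolutions, exact-adjoint transposed convolutions, manual backprop),
  and `FastUnetSegmenter` wraps it in a scikit-learn estimator interface.
- **`renalus.sagittal`** — KL as the farthest contour point pair
  (exhaustive search), tailored square crop, rotation to horizontal with
  an invertible affine record, the vertical KT caliper, and parenchymal
  thickness between the upper capsule contour and the sinus.
- **`renalus.axial`** — PCA principal-axis orientation, hilum-side
  detection from the >= 4-boundary-crossing signature, the hilum-aware
  axial thickness caliper, kidney width as the largest upper-to-lower
  nearest-contour distance, and inverse rotation of all landmarks.
- **`renalus.metrics`** — DSC, Jaccard, MAD, Hausdorff and symmetric
  surface distance, the ellipsoid volume, and a (documented,
  non-canonical) biomarker agreement evaluator.
- **`renalus.phantom`** — seeded synthetic sagittal/axial kidney phantoms
  (bean/ellipse capsule, enclosed sinus, hilum notch, multiplicative
  speckle) with exact continuum ground truth for all five biomarkers.
- **`renalus.cli`** — `renal phantom|train|segment|measure|evaluate-seg|
  evaluate-biomarkers|flops`.

## Worked example

Measure a phantom study from its ground-truth masks:

```python
from renalus import (PhantomParams, generate_sagittal_phantom,
                     generate_axial_phantom, kidney_volume)
from renalus.io import measure_sagittal, measure_axial

sag = PhantomParams(capsule_semi_major_px=150, capsule_semi_minor_px=60,
                    rotation_deg=12.0, spacing_mm_per_px=0.3, seed=7)
image, capsule, sinus, truth = generate_sagittal_phantom(sag)
m = measure_sagittal(capsule, sinus, sag.spacing_mm_per_px)

ax = PhantomParams(capsule_semi_major_px=110, capsule_semi_minor_px=50,
                   rotation_deg=-8.0, hilum_notch_depth=0.4,
                   spacing_mm_per_px=0.28, seed=8)
_, capsule_a, truth_a = generate_axial_phantom(ax)
ma = measure_axial(capsule_a, ax.spacing_mm_per_px)

volume = kidney_volume(m["KL"].length_mm, ma["KW"].length_mm, m["KT"].length_mm)
```

which prints, against the analytic truth of the generating geometry:

```
KL  89.9 mm (truth 90.0)
KT  36.0 mm (truth 36.0)
PT  22.8 mm (truth 22.5)
KW  27.7 mm (truth 28.0)
Vol 46.9 ml (truth 47.4)
```

KL is the longest capsule chord; KT is the vertical caliper after the KL
axis is rotated horizontal; PT (parenchymal thickness) is the largest
nearest-distance from the upper capsule contour to the sinus; KW comes
from the axial view; the volume combines sagittal KL/KT with axial KW.

The same chain runs from a trained model instead of reference masks via
`renalus.io.measure_study` or `renal measure --capsule-model ...`, and

```
renal flops
```

prints the per-layer FLOPs table of the default architecture
(total 1.472e10 for a 320x480 single-channel input).

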