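# Methods

## Model

`winstitch` treats patch-based segmentation stitching as windowed
overlap-add, the classical signal-processing construction for artefact-free
segment recombination. An image is tiled with square patches of side `I` at
stride `I/2`; an `n × m`-patch image therefore yields `(2n−1)(2m−1)`
overlapping patch positions (≈4× the `nm` of naive tiling), and every
interior pixel is covered by exactly four patches. Each per-patch
prediction — an `I × I × C` map of class scores from an arbitrary,
user-supplied predictor — is multiplied by a 2-D window and summed at its
absolute position.

The central requirement on a window family is the **partition of unity**:
all tiled windows, including the border variants, sum to exactly 1 at
every pixel. It makes the reconstruction a convex per-pixel combination of
the covering predictions (so a patchwise-consistent predictor is
reconstructed exactly) and removes the need for a renormalising division,
which would introduce its own rounding error.

### Window profiles and the periodic convention

All separable windows use the periodic sampling `w(i) = f(i/I)`,
`i = 0 … I−1`, *not* the symmetric `i/(I−1)` found in window-function
tables. The two differ by a single sample, but only the periodic form
satisfies `w(k) + w(k + I/2) = 1`, which the half-stride tiling needs;
the symmetric form deviates from a constant field by ~5% at `I = 64`
(demonstrated by a test). The symmetric variants remain available behind
`strict_paper=True` for comparison. For the same reason the Bartlett-Hann
profile is implemented with a *negative* triangle term,
`a₀ − a₁|i/I − ½| − a₂cos(2πi/I)`: with a positive `a₁` the profile
neither vanishes at the border nor tiles to 1 (also available behind the
flag).

### Edge and corner variants

At an image border the overlapping neighbour that would supply the
complementary weight is missing, so border patches receive per-axis
modified profiles: on an axis where the patch touches the low border,
indices `0 … I/2−1` of the profile are replaced by 1; on the high border,
indices `I/2 … I−1` (the boundary index `I/2` belongs to the flat side —
a half-open convention chosen so that the flat average window's variants
also tile to 1; for tapering profiles `w(I/2) = 1` and the choice is
invisible). A patch spanning a whole axis (single-patch direction) gets
the constant-1 profile. The four edge windows, four corner windows, and
the all-flat single-patch window are all outer products of these axis
factors, so partition of unity reduces to the 1-D identity per axis.
Mirror symmetry between opposite variants holds on indices `1 … I−1`; the
periodic index-0 sample has no counterpart.

### Pyramidal window

The distance-ratio window `W = α·Dᵉ/(Dᶜ+Dᵉ)` weighs each pixel by its
relative distance to the patch border. `Dᵉ` is the distance to the nearest
border-ring pixel — for an axis-aligned rectangle the Chebyshev, Euclidean
and cityblock metrics coincide at `min(i, I−1−i, j, J−1−j)` — and `Dᶜ` is
the Euclidean distance to the geometric centre `((I−1)/2, (J−1)/2)`
(metric configurable). `α = I·J / Σ Dᵉ/(Dᶜ+Dᵉ)` scales the weights to mean
exactly 1. The window is not separable, is zero on the entire border ring,
and its tiled field is far from constant, so the reconstruction divides by
the assembled field. Pixels of the outermost image ring are covered only
by patch border rings and accumulate zero weight; they are filled from the
nearest positively-weighted pixel (EDT nearest-index lookup) with a
warning, or reported as an error with `ring_fallback=False`. This is the
structural disadvantage the partition-of-unity windows avoid.

## Synthetic benchmark

The simulator stands in for a stained-tissue dataset and a trained
network, reproducing the *conditions* under which stitching artefacts
arise rather than tissue appearance.

**Scenes.** Non-overlapping random ellipses (semi-axes 8–20 px at the
1024² reference geometry, 8–18 px at the 512² benchmark scale) on a flat
background, labelled with three classes: background, object, and a 2-px
object-edge band (object pixels within Euclidean distance 2 of
background). Blobs stay `edge_band + 2` px clear of the image border —
nuclei fully in view — which also keeps the outer image ring constant.
The rendered image maps classes to intensities 0.1 / 0.8 / 0.5 plus mild
i.i.d. Gaussian noise (σ = 0.02).

**Predictor.** The ground-truth one-hot map, corrupted per patch by
additive Gaussian noise truncated at 0 and renormalised to the simplex.
The per-pixel noise σ is `base + edge·(1−d)²` with `d` the normalised
distance to the patch border: σ = 0.02 at patch centres and 0.50 on the
border ring, giving a border label-flip rate of roughly 15–20% — an
error profile consistent with the reported degradation of CNN predictions
near patch edges and corners. Noise is drawn independently per patch
origin (stream seeded by `(seed, row, col)`), so overlapping patches
disagree near their borders — the regime where centre-weighted windows
help and flat averaging imports noise into clean regions.

What the simulator does *not* model: correlated (structured) prediction
errors, class-dependent error rates, texture, staining variation, or any
actual network. Passing benchmarks here demonstrates that the stitching
machinery behaves as the theory predicts under border-localised error;
it does not certify improvements on any particular real dataset, where
the error profile is a property of the trained model.

## Evaluation protocol

Artefacts occupy a small pixel fraction, so raw scores barely separate
methods. The protocol: (1) class-wise SSIM — the standard structural
similarity per class channel on soft probabilities (7-px uniform window,
standard stabilising constants, data range 1.0), averaged over the three
classes; (2) micro and macro Dice on the argmax labels (ties broken
toward the lowest class index, deterministically), computed separately
inside and outside an *edge-vicinity mask* marking pixels within
`half_width` of any interior boundary of the non-overlapping tiling
(default half-width 5 px, recorded in the run config; a class absent from
both prediction and truth in a region contributes a per-class Dice of 1,
configurable to be skipped); (3) all scores reported *adjusted*, minus
the no-overlap baseline on the same image, cancelling simulator/predictor
difficulty; (4) paired comparisons across scenes with a one-sample t-test
on the per-image differences (df = n−1, two-sided; zero-variance
differences reported as degenerate rather than NaN) and a two-sided exact
binomial sign test with ties dropped.

## Problem sizes and numerics

The default benchmark runs 14 independent scenes of 512×512 px with
128×128 patches (49 overlapping / 16 baseline patches per scene) — a
scene count matching the reference protocol and a scene size that keeps
the full six-method comparison under a minute on one core while leaving
7×7 interior grid lines for the edge-vicinity statistics. The
partition-of-unity and exact-reconstruction checks run at the full
1024×1024 / 128 reference geometry.

Windows are built and accumulated in float64; the assembled field then
deviates from 1 by < 1e−15 per pixel and the identity-reconstruction
property holds to 1e−6 with margin. Non-multiple image extents are
reflect-padded (bottom/right) to the next patch multiple and cropped back
bit-exactly; reflection avoids creating an artificial intensity edge.
Odd patch sizes are rejected outright (the half stride and the variant
quadrant split both need `I/2` integral) rather than rounded.

## Known limitations

- Square patches and half-patch stride only; the partition-of-unity
  guarantee is specific to 50% overlap, so other stride ratios are out of
  scope by design.
- The pyramidal outer-ring fill is a nearest-neighbour heuristic; the
  alternative (dropping the ring) changes image extent.
- The simulated predictor's noise is pixel-independent; real CNN errors
  are spatially correlated, which would widen the variance of all scores
  but not change which pixels the windows down-weight.
- SSIM is computed on soft probability channels; binarising first is a
  reasonable alternative convention and would shift absolute values.
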