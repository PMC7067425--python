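# winstitch

Windowed overlap-add stitching for patch-based image segmentation.

Convolutional segmentation networks cannot ingest gigapixel images — whole
slide images in digital pathology, large microscopy mosaics — so prediction
runs on fixed-size patches that must be recombined. Naive tile concatenation
leaves visible grid artefacts, because CNN predictions degrade toward patch
borders and are worst in corners. `winstitch` removes these edge effects
*post hoc*, with no retraining and no change to the model: patches are
extracted at a stride of half a patch, each per-patch prediction is
multiplied by a 2-D window function that emphasises the patch centre, and
the weighted patches are summed at their absolute positions.

## The method

A separable 2-D window is the outer product of a 1-D profile,
`W(i, j) = w(i) w(j)`. Profiles are built in the *periodic* convention
(denominator `I`, the patch side), because only that form tiles to a
constant at 50% overlap:

| kind | `w(i)`, `i = 0 … I−1` |
|---|---|
| average | `1/2` |
| hann | `(1 − cos(2πi/I)) / 2` |
| bartlett_hann | `a₀ − a₁·\|i/I − 1/2\| − a₂·cos(2πi/I)`, `a₀=0.62, a₁=0.48, a₂=0.38` |
| triangular | `1 − \|2i/I − 1\|` |

These windows form a **partition of unity**: tiled at half-patch stride,
with dedicated edge and corner variants whose outward-facing halves are
flat (weight 1, compensating for the missing neighbour at the image
border), they sum to exactly 1 at every pixel. Reconstruction is therefore
a single weighted sum — no renormalisation, no extra floating-point error.

The **pyramidal** window, `W = α·Dᵉ/(Dᶜ + Dᵉ)` with `Dᵉ` the distance to
the patch border, `Dᶜ` the distance to the patch centre and `α` a mean-1
normaliser, is included for comparison. It is not separable, does not
partition unity (it is zero on every patch's border ring), and its
reconstruction must divide by the assembled weight field.

Because no public dataset or trained network is required, the package ships
a synthetic benchmark: a 3-class scene generator (background / object /
object-edge, nuclei-like elliptical blobs) and a simulated predictor whose
noise grows toward patch borders, drawn independently per patch. The
evaluation protocol scores each stitching method against ground truth with
class-averaged SSIM and with micro/macro Dice split between patch-centre
pixels and an edge-vicinity mask around the tile boundaries, reports every
score adjusted by the no-overlap baseline, and compares methods with a
paired t-test and an exact sign test.

## Worked example

Run the full comparison — 14 simulated 512×512 scenes, 128×128 patches,
six stitching methods:

```sh
winstitch benchmark --seeds 14 --out scores.csv --tests-out tests.json
```

which prints the mean ± sd of the baseline-adjusted scores (method score
minus the no-overlap baseline's score on the same image; positive = better
than naive tiling):

```
metric     region        method
ssim       all           average       -0.00454  0.00091
                         bartlett_hann  0.06406  0.00062
                         hann           0.07098  0.00065
                         no_overlap     0.00000  0.00000
                         pyramidal      0.04423  0.00066
                         triangular     0.04528  0.00067
dice_micro centre        hann           0.01488  0.00020
           edge_vicinity hann           0.10873  0.00169
```

(excerpt). Reading this: every tapering window improves SSIM on every
scene — the Hann window most — while the flat average window *hurts* SSIM
relative to the baseline, because overlapping patches import border noise
into otherwise clean regions at full weight. The Dice rows show the gain is
where it should be: the Hann window's micro-Dice improvement in the
edge-vicinity band (+0.109) is seven times its improvement in patch
centres (+0.015). Pairwise paired-t p-values between all methods are
written to `tests.json`.

The same pieces are available as a library:

```python
import winstitch as ws

image, gt = ws.generate_scene(ws.SceneSpec(height=512, width=512, n_blobs=30, seed=7))
grid = ws.plan_grid(512, 512, 128)
predictor = ws.noisy_edge_predictor(gt, grid, ws.ArtefactProfile(seed=7))
prob = ws.reconstruct(image, predictor, "hann", patch=128)   # (512, 512, 3)
print(ws.ssim_classwise(prob, gt))
```

Any callable `predictor(patch, origin) -> (I, I, C)` works in place of the
simulator — wrap your own model's forward pass and stitch its output.

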