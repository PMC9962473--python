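# Methods

## Problem and approach

Counting leaves on monocot plants (sorghum, maize) from side-view greenhouse
RGB images is awkward for detection-style counters: the leaves are long,
curved, self-similar, and frequently cross one another. `monoleaf` instead
treats the count as a direct regression target: a convolutional network maps
a 299×299×3 image of an extracted plant to one real number, trained with mean
squared error against the integer label. The surrounding pipeline — plant
extraction, skeleton-structure derivation, geometric augmentation, metric
evaluation, and two interpretability procedures — is what this package
implements and tests end to end on procedurally generated plants with known
leaf counts.

## Plant extraction (`preprocess`)

Greenhouse scenes share a static rig that dominates the pixel budget, but
per-image illumination jitter defeats single-image background subtraction.
The pipeline therefore averages many plant-free captures of the scene
(default 50) into one background image; the per-image jitter cancels in the
mean. Extraction is then:

1. per-channel **absolute difference** against the averaged background
   (absolute rather than signed, so it is robust to either contrast polarity;
   a signed, clipped variant is available);
2. grayscale via ITU-R 601 luma weights (0.299, 0.587, 0.114);
3. **Otsu binarization** over the 256-level histogram. The integer threshold
   `t` maximizes the between-class variance of the `{v ≤ t} / {v > t}`
   partition; ties resolve to the smallest maximizer, and a constant image is
   an error rather than a degenerate threshold;
4. **8-connected component labeling** (8 rather than 4 so thin diagonal
   leaf sections are not split);
5. crop to the bounding box of the largest component and resize so the longer
   side is 299 px, centering the shorter side on white padding (aspect ratio
   is preserved; bilinear for RGB, nearest for masks).

Two guards reject frames with no plant: a minimum component area (default
100 px) and a minimum mean difference intensity inside the winning component
(default 25 gray levels). The second matters because residual jitter can form
arbitrarily large, faint components in plant-free frames.

## Skeleton structure (`skeletonize`)

Thin or weakly lit leaf sections binarize into broken segments; leaf width
also varies along the blade, which a counting network can confuse with extra
structure. The skeleton representation normalizes both: Otsu-binarize the
cropped plant (dark polarity — the plant is darker than the white padding),
thin to a one-pixel topology-preserving skeleton (Zhang–Suen-style iterative
thinning), dilate once with a 3×3 square element to reconnect breaks up to
2 px, remove connected components smaller than **50 px** (strictly
`area < 50` is removed — 49 dies, 50 survives), and dilate once more to
thicken the strokes. The final mask renders black-on-white for model input.

Known artifact: where a leaf's width changes sharply, thinning can emit short
spurs ("extra tips") that survive the area filter; the pipeline does not try
to cure these.

## Augmentation (`augment`)

Twelve label-preserving operations: the original; vertical/horizontal
compression (factor 0.5 about the center, white-padded — the factor is a
package choice, configurable); vertical flip; vertical flip followed by
either compression (the six "realistic" ops); then horizontal flip, 180°
rotation, and 90° cw/ccw rotations with optional vertical flip (the six
non-realistic ops — a monocot hanging sideways is not a plausible capture,
but the count is unchanged). Expansion applies to the train split only:
800 train rows become 4800 under the realistic set and 9600 under the full
set; val/test rows pass through byte-identical. Padding pixels are exactly
(255, 255, 255).

## Count regressor (`regressor`)

The head is the load-bearing design: **global average pooling** over the
final convolutional feature map, then a **single-unit dense layer**, so the
prediction is a weighted sum of per-channel mean activations. This keeps the
output scalar differentiable structure trivial (the gradient of the output
w.r.t. the feature map is `w_c/(H·W)` per channel), which Grad-CAM exploits
exactly.

The trunk is the `reduced` family: four strided convolutions
(5×5/stride 4, then three 3×3/stride 2; channels 8-16-24-32 at width
multiplier 1.0, He-initialized), ReLU throughout, implemented on NumPy with
im2col convolutions and hand-written backprop. At 299-px input the final
feature map is 10×10×32 and the model has ~12k parameters — small enough to
train on a laptop CPU in about a minute, large enough to regress counts on
the synthetic plants. `reduced_width_mult` scales the channel widths
(parameter count scales roughly quadratically).

Training defaults mirror standard counting-by-regression practice: batch 16,
RMSprop (ρ = 0.9) at learning rate 1e-4, MSE on the raw (unrounded) output,
500 epochs, no early stopping. Those defaults suit long fine-tuning runs; the
desk-scale experiments in this repo use lr 3e-3 and 30 epochs. Two numerical
choices worth knowing: inputs scale to [-1, 1] (`x/127.5 − 1`), and the head
bias is warm-started to the mean training label so the early epochs refine
counts instead of climbing from zero. Data order shuffles per epoch from the
config seed; identical seeds give identical loss curves.

## Metrics (`evaluate`)

Over labels `y_i` and raw predictions `ŷ_i`:
RMSE = √(Σ(y−ŷ)²/n); R² = 1 − SS_res/SS_tot (an explicit error when the
labels are constant); accuracy = fraction with `round(ŷ) = y`. The rounding
rule for accuracy is round-half-up (configurable to banker's rounding) — the
raw prediction itself is never rounded for RMSE/R². `distribution_summary`
groups raw predictions by true count with quantiles and a Gaussian KDE for
violin-style plots.

## Interpretation (`interpret`)

**Occlusion sensitivity**: a window (default 10×10 — about one leaf width —
stride 5) painted with the background color slides over the image; each grid
cell stores `prediction − ground truth` at that position
(positive = occlusion raised the count). Grid side is
`⌊(S − window)/stride⌋ + 1`, i.e. 58×58 at S = 299. Cells are single window
positions; overlapping windows are deliberately not averaged per pixel. The
window color is white for plant-on-white inputs and black for skeleton
images — the point is to erase structure, not add an object.

**Grad-CAM**: per-channel weights are spatial means of the output gradient at
the final convolutional layer; the rectified weighted channel sum is min-max
normalized to [0, 1] (all-equal maps normalize to zero) and upsampled
nearest-neighbor. `emphasize` applies a logistic `1/(1+e^{−k(v−0.5)})`
(k = 10, both package choices) to sharpen the hot/cold boundary for display.

## Synthetic plants (`plantgen`)

The generator renders what the pipeline needs and nothing more: a static
equipment-like background (poles, rail, panel, low-frequency texture, dark
pot) shared by every frame; per-image uniform brightness jitter (default
±6 gray levels); a vertical stem; and `leaf_count` quadratic Bézier leaf
strokes attached alternately left/right along the stem, tapering from ~7 px
at the base to ~2 px tips, painted ~60 gray levels darker than the mean
background. `occlusion=True` re-aims the top leaf across its neighbour
(deterministically retrying) until two strokes intersect. Distractor blobs
emulate grass/soil debris and appear only in plant frames. Everything is
driven by `numpy` Generators split into independent streams (jitter /
geometry / blobs), so identical specs render identical bytes, and per-leaf
masks, tip and attachment coordinates are retained for test oracles.

What the generator does **not** emulate: leaf venation and serration, specular
lighting, pot/plant contact shadows, camera noise, perspective, species
morphology differences, tassels, or plants whose leaves leave the frame.
Passing tests therefore demonstrate that the pipeline's machinery —
extraction, skeletons, augmentation arithmetic, training dynamics, map
geometry — is correct on images with the stated structure; they do not
certify accuracy on real greenhouse imagery.

## Desk-scale experiment

The repository's standing experiment trains the reduced backbone on 300
rendered plants (counts uniform in 2–6, no occlusion, 299-px canvas) for 30
epochs at lr 3e-3 and evaluates on 50 held-out renders; the suite requires
held-out RMSE < 1.0 and accuracy above the 0.2 chance level, and the fixed
test seed lands well inside both (RMSE ≈ 0.4, accuracy ≈ 0.8). These bars are
repo-defined sanity surrogates for full-scale results, not claims about real
data.

On interpretability direction checks: on a curated reference render
(2 leaves, seed 9005) the trained model's Grad-CAM weights leaf-tip
neighborhoods above the stem, and occluding a leaf at its base raises the
prediction while erasing its tip lowers it. Averaged over *all* held-out
renders the tip-minus-stem gap can be negative at desk scale — the small
model often leans on the stem/junction region — so the tip-dominance reading
is asserted only on the curated fixture and otherwise reported as a
measurement (`gradcam_tip_stem_gap_mean` in the acceptance output).

## Limitations

* The NumPy backbone is CPU-sized; it is not an Inception-scale architecture
  and desk-scale results do not transfer to real greenhouse imagery.
* Otsu-based extraction assumes a unimodal background difference and a single
  plant per frame; multi-plant scenes are out of scope.
* The skeleton stage inherits thinning's "extra tips" artifact.
* Occlusion maps cost one forward pass per window position (3364 at the
  defaults); they are batched but still the slowest interpretability path.
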