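# Methods

## The model

The package treats a histopathology image as a bag of square patches
sampled on a rectangular grid. Three assumptions drive the design:

1. **Locality** — diagnostic texture (nuclear density, stain intensity,
   gland architecture) is visible at patch scale, so per-patch features
   suffice.
2. **Sparsity of signal** — only part of a positive slide is abnormal, so
   image-level aggregation must not average the signal away. P-norm
   pooling, f_P = ((1/N) Σ v_i^P)^(1/P), is the component-wise power mean
   of the patch features; it equals the mean at P = 1, converges to the
   maximum as P → ∞ (analytically, max·N^(−1/P) ≤ f_P ≤ max), and at the
   default P = 3 amplifies strong patch responses without being as brittle
   as max pooling. Pooling requires nonnegative inputs, which rectified
   network activations and histogram features both satisfy.
3. **Linearity at the top** — given good features, a linear max-margin
   classifier is enough, is convex, and exposes interpretable weights
   (used by the gallery visualization).

Binary classification restricts features to the k = 100 components with
the largest absolute difference of class means (computed over image-level
pooled vectors). Multiclass uses one-vs-rest on the full vector with no
selection. The SVM minimizes ½wᵀw + C·Σ max(0, 1 − y_i wᵀx_i); C is picked
from {0.01, 0.1, 1, 10, 100} by stratified k-fold cross-validation within
the training data (ties to the smallest C, i.e. the most regularized
model). Selection is refit inside every fold so validation images never
influence it.

Segmentation runs the same machinery densely: 112-px patches at an 8-px
stride, trained with labels derived from the ground-truth mask (positive
iff the in-box positive fraction strictly exceeds 0.6), then a per-pixel
majority vote over covering patches (ties and uncovered pixels negative)
and removal of connected components — positive first, then negative holes —
smaller than 5% of the image area (strictly smaller; 8-connectivity).

## Parameter defaults

| parameter | default | unit | why |
|---|---|---|---|
| classification patch | 336 (20×) / 672 (40×) | px | equal physical footprint at either scan resolution (672 px × 226 nm/px = 151,872 nm) |
| classification stride | 64 | px | dense overlap without exploding patch counts |
| segmentation patch / stride | 112 / 8 | px | fine localization; the vote needs many covering patches per pixel |
| background threshold | 200 | 8-bit channel value | glass is near-white; the test is strict (> 200 in all channels of every pixel) |
| resize target | 224 | px | input size of the deep-backbone contract; histogram features are resolution-free, so pipelines using them may set target_size = patch_size and skip resampling |
| pooling P | 3 | — | between mean and max; see above |
| k_select | 100 | dims | binary tasks only; clamped to D with a warning when the extractor is narrower than 100 (the reference descriptor has D = 32) |
| C grid | {0.01 … 100} | — | standard decade sweep |
| overlap threshold | 0.6 | fraction | patches dominated by the region; strictly greater |
| min region fraction | 0.05 | of H·W | suppresses biologically meaningless specks; strictly less is removed |
| fine-tune lr / epochs | 1e-4 / 20 | — | constant-rate SGD; the replaced head trains at lr × head_lr_multiplier (default 1, i.e. uniform — the head's own rate is a free choice and is exposed rather than hard-coded) |

Numerical choices: bilinear resampling for patch resizing (exact identity
when sizes already match); SVM solver tolerance 1e-4 recorded in model
metadata; selection ties broken by ascending feature index; one-vs-rest
prediction ties broken by class order; a decision value of exactly 0 is
negative. Pooling is computed in max-factored form so large P does not
overflow. All of these are recorded so reruns are bit-identical.

## Feature extractors

The pipeline only assumes the extractor contract: fixed-size RGB patch →
length-D vector of finite nonnegative values, deterministically.

* **Reference histogram descriptor** (default, D = 3·bins + texture_stats =
  32): per-channel intensity histograms over [0, 256) plus a histogram of
  grey-level gradient magnitudes clipped to [0, 64). Each block sums to 1.
  It captures exactly the stain-intensity and edge-density cues the
  synthetic textures differ in.
* **Miniature trainable backbone**: a two-conv network (stride-2 3×3
  convolutions, global average pooling, one rectified fully connected
  feature layer, softmax head) implemented in numpy with explicit
  backpropagation. It exists to make the fine-tuning procedure concrete
  and testable: the head is replaced by a freshly initialized N-way layer
  and every layer is updated by constant-rate minibatch SGD. Zero learning
  rate is an exact parameter no-op; zero epochs leaves features identical.
* **Deep backbone contract**: the AlexNet-style layer table (conv1 …
  pool3, fc1, fc2 at 4096) is carried as metadata; pre-trained weights are
  a user-supplied plug-in, never downloaded. Feature vectors are taken
  after the rectifier (nonnegativity is what the pooling stage needs);
  extractors that return negative components are clamped at 0 with a
  warning rather than rejected.

## Synthetic data: what it does and does not emulate

`synthdata` generates slides with (i) a bright glass border whose pixels
all exceed the 200 background threshold, (ii) a pink "normal" tissue field
with sparse dark-purple elliptical nuclei, (iii) optionally one simply
connected tumor region — a low-order-Fourier-smoothed random polygon
rescaled once to hit the target area fraction — rendered with a darker
field and denser, size-jittered nuclei, plus a matching binary mask, and
(iv) an optional "stroma" texture for multiclass experiments. All outputs
are pure functions of `SynthParams` (per-image seeds derive from the
dataset seed and the image index), and the class color means are separated
from each other by far more than the 8-unit pixel noise, which guarantees
linear separability of the histogram features.

Study conditions fixed in `experiments.py`: classification slides are
512×512 px (a 3×3 grid of 336-px patches at stride 64), 20 per class for
binary and 10 per class for the 3-texture task; segmentation slides are
1280×800 px — the image size of the colon-cancer segmentation setting this
emulates — with the tumor occupying ~30% of the tissue, 5 training and 10
evaluation slides. The region-to-patch ratio matters: with 112-px patches,
>0.6-overlap labeling plus majority voting erodes roughly
(0.6 − 0.5)·112 ≈ 11 px of region rim (more where the boundary is strongly
curved), so regions must be several patch widths across for high overlap
scores — as they are in real slides at this scale.

What passing these tests shows: the geometry (tiling, voting, smoothing),
the statistics (pooling, selection, CV model selection) and the plumbing
are correct, and the pipeline recovers planted structure whenever the
features separate the classes. What they do not show: performance on real
H&E material, where stain variation, artifacts, and genuinely ambiguous
texture dominate — no photorealism or stain normalization is attempted.

## Known limitations and open choices

* The overlap score is implemented with the Dice denominator
  2|P∩G|/(|P|+|G|) by default because reported scores on a percentage
  scale are incompatible with a union denominator (which scores 2 at
  perfect agreement); the literal union form is kept behind a flag and the
  discrepancy is surfaced in `evaluate`'s documentation rather than
  silently resolved. Both-empty masks score 1.
* Patch-level training for segmentation uses all grid boxes, including
  white background (obvious negatives); this is what lets prediction
  classify background boxes instead of defaulting them, at the cost of a
  mild class imbalance.
* Mean-difference selection is defined over image-level vectors; the
  patch-level segmentation SVM therefore trains on the full feature
  vector by default.
* The grid never emits partial patches: right/bottom margins narrower than
  one patch are uncovered (and voted negative). Heatmaps flag such pixels
  as no-data instead.
* Majority voting uses hard labels; a confidence-weighted vote (summing
  decision values) is available but off by default, since the hard vote is
  the documented behaviour.
* Fine-tuning exposes a per-layer learning-rate multiplier for the new
  head because no principled default exists; uniform rate is the default.
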