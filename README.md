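# histopatch

Patch-based classification and segmentation of large histopathology images.

Digitized H&E slides are far too large to featurize whole, and their
diagnostic signal is often carried by a small part of the tissue. This
package implements the classic patch-based answer to both problems:

**Classification.** Each image is divided into overlapping square patches on
a rectangular grid (336 px at 20× magnification, 672 px at 40×, 64-px
stride). Patches that are pure glass — every pixel with R, G and B above
200 — are discarded; the rest are resized to the feature extractor's input
size and mapped to nonnegative feature vectors v_i. One image-level vector
is formed by **P-norm (softmax) pooling**,

    f_P = ( (1/N) Σ_i v_i^P )^(1/P),     P = 3 by default,

which interpolates between the mean (P = 1) and the component-wise maximum
(P → ∞), amplifying the few strongest patch responses. For binary tasks the
most discriminative components are kept by ranking the absolute difference
of class means over image-level features,

    diff_k = | mean_{i∈pos} v_{i,k} − mean_{i∈neg} v_{i,k} |,

and selecting the top k (default 100). An L2-regularized linear SVM
(hinge loss, C chosen from {0.01, 0.1, 1, 10, 100} by stratified
cross-validation on training data) classifies the result; multiclass tasks
use one-vs-rest on the full feature vector.

**Segmentation.** 112-px patches at an 8-px stride are classified
positive/negative by a linear SVM trained on patches whose overlap with the
annotated region exceeds 0.6; each pixel takes the **majority vote** of the
patches covering it, and connected regions smaller than 5% of the image are
removed (positives pruned first, then holes filled). Segmentations are
scored per image against ground truth with a Dice-style overlap
(2|P∩G| / (|P|+|G|) by default; the literal 2|P∩G| / |P∪G| variant is
available behind a flag) and averaged.

Feature extraction is pluggable. A deterministic histogram descriptor
(per-channel intensity histograms plus a gradient-magnitude texture
histogram) ships as the reference extractor; a miniature trainable
convolutional backbone demonstrates the fine-tuning recipe (replace the
classification head, constant-rate SGD through all layers); a deep
AlexNet-style backbone can be plugged in from user-supplied weights.
Everything is exercised on a seeded synthetic slide generator — white glass
border, pink tissue with scattered dark nuclei, and a contiguous
denser/darker "tumor" region with a matching ground-truth mask — so the
whole pipeline is testable without any slide downloads.

## Worked example

```python
import histopatch as hp
from histopatch.experiments import binary_classification_cv, segmentation_experiment

# one synthetic slide
image, mask, label = hp.make_slide(hp.SynthParams(seed=0))
ext = hp.reference_extractor()                      # D = 3*8 + 8 = 32
feat = hp.image_feature(image, ext, hp.TilingConfig())
print(label, feat.shape)                            # tumor (32,)

# 40-slide binary pipeline under 5-fold cross-validation
print(binary_classification_cv(seed=0, n_per_class=20))   # 1.0

# patch-vote segmentation on 10 fresh 1280x800 slides
mean_score, per_image = segmentation_experiment(seed=0)
print(round(mean_score, 3))                          # 0.947
```

The CV accuracy of 1.0 reflects the generator's separability guarantee (the
two textures differ in nuclear density and stain intensity by far more than
the pixel noise); the segmentation score of ≈0.95 is limited by boundary
granularity — patch labeling at the 0.6 overlap threshold plus majority
voting erodes roughly a patch-fraction of the region rim.

The same operations are available from a CLI:

```bash
histopatch synth classify --n-per-class 20 --seed 0 --out data/cls
histopatch train-cls --manifest data/cls/manifest.csv --seed 0 --out runs/cls
histopatch predict-cls --model runs/cls/model --image data/cls/images/slide_000.png
histopatch synth segment --n 5 --seed 0 --out data/seg
histopatch train-seg --manifest data/seg/manifest.csv --seed 0 --out runs/seg
histopatch predict-seg --model runs/seg/model --image data/seg/images/slide_000.png --out pred.png
histopatch evaluate --pred runs/seg/masks --truth data/seg/masks
histopatch heatmap --model runs/seg/model --image data/seg/images/slide_000.png --out heat.png
```

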