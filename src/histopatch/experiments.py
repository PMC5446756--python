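"""Desk-scale benchmark protocols on synthetic slides.

These functions define the package's reference experiments — the synthetic
stand-ins for full-dataset benchmarks — with their study conditions fixed:

* Binary classification: 20 tumor + 20 normal slides of 512x512 px,
  336-px patches at a 64-px stride resized to 224, reference histogram
  features, P = 3 pooling, top-k mean-difference selection, 5-fold
  stratified cross-validation with the C grid searched inside each
  training fold.
* Three-class classification: 10 slides each of normal, tumor and stroma
  textures, one-vs-rest on the full feature vector.
* Segmentation: 1280x800 px slides (the image size of the colon
  segmentation setting this emulates), 112-px patches at an 8-px stride,
  >0.6-overlap patch labeling, per-pixel majority vote, 5% region
  smoothing; the patch classifier trains on 5 slides and is evaluated on
  10 fresh ones by the Dice-denominator overlap score.  Features are
  computed at the native 112-px patch size because the histogram
  descriptor has no fixed input resolution.

All randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import StratifiedKFold

import histopatch as hp
from histopatch.evaluate import classification_accuracy, score_masks

CLS_IMAGE_SIZE = 512
SEG_IMAGE_WIDTH = 1280
SEG_IMAGE_HEIGHT = 800


def _cls_params(seed: int, classes=("normal", "tumor")) -> hp.SynthParams:
    return hp.SynthParams(
        seed=seed,
        image_height=CLS_IMAGE_SIZE,
        image_width=CLS_IMAGE_SIZE,
        texture_classes=tuple(classes),
    )


def _seg_params(seed: int) -> hp.SynthParams:
    return hp.SynthParams(seed=seed, image_height=SEG_IMAGE_HEIGHT, image_width=SEG_IMAGE_WIDTH)


def pooled_dataset(records, extractor=None, tiling_cfg=None, pooling_cfg=None):
    """Image-level pooled feature matrix and label vector for a record list."""
    extractor = extractor or hp.reference_extractor()
    tiling_cfg = tiling_cfg or hp.TilingConfig()
    feats = np.vstack(
        [hp.image_feature(r["image"], extractor, tiling_cfg, pooling_cfg) for r in records]
    )
    labels = np.array([r["label"] for r in records])
    return feats, labels


def binary_classification_cv(seed: int = 0, n_per_class: int = 20, cv_folds: int = 5) -> float:
    """Mean held-out accuracy of the binary pipeline under 5-fold CV."""
    records = hp.make_classification_dataset(n_per_class, _cls_params(seed))
    feats, labels = pooled_dataset(records)
    cfg = hp.TrainConfig(seed=seed)
    accs = []
    for tr, va in StratifiedKFold(cv_folds, shuffle=True, random_state=seed).split(feats, labels):
        model = hp.train_binary(feats[tr], labels[tr], cfg)
        accs.append(classification_accuracy(model.predict(feats[va]), labels[va]))
    return float(np.mean(accs))


def multiclass_classification_cv(seed: int = 0, n_per_class: int = 10, cv_folds: int = 5) -> float:
    """Mean held-out accuracy of one-vs-rest 3-class classification."""
    records = hp.make_classification_dataset(
        n_per_class, _cls_params(seed, classes=("normal", "tumor", "stroma"))
    )
    feats, labels = pooled_dataset(records)
    cfg = hp.TrainConfig(seed=seed)
    accs = []
    for tr, va in StratifiedKFold(cv_folds, shuffle=True, random_state=seed).split(feats, labels):
        model = hp.train_multiclass(feats[tr], labels[tr], cfg)
        accs.append(classification_accuracy(model.predict(feats[va]), labels[va]))
    return float(np.mean(accs))


def segmentation_experiment(seed: int = 0, n_train: int = 5, n_test: int = 10):
    """Train the patch classifier and score segmentations on fresh slides.

    Returns the mean Dice-style overlap score over the test slides and the
    per-slide scores.
    """
    train = hp.make_segmentation_dataset(n_train, _seg_params(seed))
    test = hp.make_segmentation_dataset(n_test, _seg_params(seed + 1))
    extractor = hp.reference_extractor()
    seg_cfg = hp.SegConfig(target_size=112)
    model = hp.train_patch_classifier(
        train, extractor, seg_cfg, hp.TrainConfig(seed=seed, k_select=None)
    )
    preds = [hp.segment_image(model, r["image"], extractor, seg_cfg) for r in test]
    report = score_masks(preds, [r["mask"] for r in test])
    return report.mean_score, report.per_image_scores
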