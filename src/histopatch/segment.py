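"""Patch-vote semantic segmentation.

Dense 112-px patches at an 8-px stride are classified positive/negative by
a linear SVM; every pixel then takes the majority label of the patches
covering it (ties and uncovered pixels are negative), and connected
positive or negative regions smaller than 5% of the image area are removed
— positives first, then negative holes are filled.

Training labels come from the ground-truth mask: a patch is positive iff
the fraction of positive pixels inside it is strictly greater than the
overlap threshold (default 0.6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as _cc_label

from histopatch.classify import LinearModel, TrainConfig, train_binary
from histopatch.errors import ConfigurationError, InputError
from histopatch.features import FeatureExtractor, extract_features
from histopatch.tiling import (
    PatchGrid,
    SlideImage,
    TilingConfig,
    crop,
    generate_grid,
    resize_patch,
)

SEG_PATCH_SIZE = 112
SEG_STRIDE = 8


@dataclass
class SegConfig:
    """Segmentation knobs: geometry, labeling threshold, smoothing, votes."""

    patch_size: int = SEG_PATCH_SIZE
    stride: int = SEG_STRIDE
    positive_overlap_threshold: float = 0.6
    min_region_fraction: float = 0.05
    tie_policy: str = "negative"
    connectivity: int = 8
    target_size: int = 224
    background_threshold: int = 200

    def __post_init__(self) -> None:
        if not (0.0 < self.positive_overlap_threshold < 1.0):
            raise InputError("positive_overlap_threshold must lie in (0, 1)")
        if not (0.0 <= self.min_region_fraction < 1.0):
            raise InputError("min_region_fraction must lie in [0, 1)")
        if self.connectivity not in (4, 8):
            raise InputError("connectivity must be 4 or 8")


def _tiling_cfg(cfg: SegConfig) -> TilingConfig:
    return TilingConfig(
        patch_size=cfg.patch_size,
        stride=cfg.stride,
        background_threshold=cfg.background_threshold,
        target_size=cfg.target_size,
    )


def label_patches_from_mask(grid: PatchGrid, mask: np.ndarray, cfg: SegConfig) -> np.ndarray:
    """Per-patch training labels from a ground-truth mask.

    Overlap ratio = positive pixels inside the box / patch_size^2; the label
    is 1 iff the ratio is strictly greater than the threshold.
    """
    m = (np.asarray(mask) > 0).astype(np.int64)
    h, w = m.shape
    s = grid.patch_size
    # integral image for O(1) box sums
    integ = np.zeros((h + 1, w + 1), dtype=np.int64)
    integ[1:, 1:] = m.cumsum(0).cumsum(1)
    labels = np.zeros(len(grid.boxes), dtype=np.int8)
    area = float(s * s)
    for i, (x0, y0) in enumerate(grid.boxes):
        if x0 + s > w or y0 + s > h:
            raise InputError(f"grid box {(x0, y0)} exceeds mask bounds {(h, w)}")
        pos = integ[y0 + s, x0 + s] - integ[y0, x0 + s] - integ[y0 + s, x0] + integ[y0, x0]
        labels[i] = 1 if pos / area > cfg.positive_overlap_threshold else 0
    return labels


def train_patch_classifier(
    records,
    extractor: FeatureExtractor,
    cfg: SegConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> LinearModel:
    """Fit the patch-level SVM from (image, mask) records.

    All grid boxes participate — white background patches are legitimate
    negatives, which is what lets prediction classify them too.  Feature
    selection is off by default at the patch level (the mean-difference
    ranking is defined over image-level vectors).
    """
    cfg = cfg or SegConfig()
    train_cfg = train_cfg or TrainConfig(k_select=None)
    tcfg = _tiling_cfg(cfg)
    feats, labels = [], []
    for rec in records:
        image, mask = rec["image"], rec["mask"]
        grid = generate_grid(image, tcfg)
        if not grid.boxes:
            continue
        patch_labels = label_patches_from_mask(grid, mask, cfg)
        patches = [resize_patch(crop(image, b, cfg.patch_size), cfg.target_size) for b in grid.boxes]
        feats.append(extract_features(extractor, patches))
        labels.append(patch_labels)
    if not feats:
        raise InputError("no training patches could be sampled")
    x = np.vstack(feats)
    y = np.concatenate(labels)
    model = train_binary(
        x,
        y.astype(int),
        train_cfg,
        extractor_name=extractor.name,
        patch_size=cfg.patch_size,
        stride=cfg.stride,
        target_size=cfg.target_size,
    )
    return model


def predict_patch_labels(
    model: LinearModel,
    image: SlideImage,
    extractor: FeatureExtractor,
    cfg: SegConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, PatchGrid]:
    """Classify every grid box of a slide (background boxes included).

    Returns (labels, decision values, grid); a decision value of exactly 0
    is negative (tie policy).
    """
    cfg = cfg or SegConfig()
    if model.extractor_name and extractor.name != model.extractor_name:
        raise ConfigurationError(
            f"model was trained with extractor {model.extractor_name!r}, got {extractor.name!r}"
        )
    if model.patch_size is not None and model.patch_size != cfg.patch_size:
        raise ConfigurationError(
            f"model was trained at patch_size={model.patch_size}, config says {cfg.patch_size}"
        )
    grid = generate_grid(image, _tiling_cfg(cfg))
    if not grid.boxes:
        return np.zeros(0, dtype=np.int8), np.zeros(0), grid
    patches = [resize_patch(crop(image, b, cfg.patch_size), cfg.target_size) for b in grid.boxes]
    feats = extract_features(extractor, patches)
    decisions = model.decision_values(feats)[:, 0]
    labels = (decisions > 0).astype(np.int8)
    return labels, decisions, grid


def vote_pixels(grid: PatchGrid, patch_labels, image_shape: tuple[int, int]) -> np.ndarray:
    """Per-pixel majority vote over covering patches.

    Positive labels count +1, negative -1 on every pixel of their box; a
    pixel is positive iff its tally is strictly positive, so ties and
    uncovered pixels are negative.  Implemented with a 2-D difference array
    (O(boxes + pixels)).
    """
    labels = np.asarray(patch_labels)
    if labels.shape[0] != len(grid.boxes):
        raise InputError("patch_labels length does not match grid")
    h, w = image_shape
    s = grid.patch_size
    diff = np.zeros((h + 1, w + 1), dtype=np.int64)
    for (x0, y0), lab in zip(grid.boxes, labels):
        v = 1 if lab > 0 else -1
        diff[y0, x0] += v
        diff[y0, min(x0 + s, w)] -= v
        diff[min(y0 + s, h), x0] -= v
        diff[min(y0 + s, h), min(x0 + s, w)] += v
    tally = diff.cumsum(0).cumsum(1)[:h, :w]
    return (tally > 0).astype(np.uint8)


def smooth_regions(mask: np.ndarray, cfg: SegConfig | None = None) -> np.ndarray:
    """Remove small connected regions, positives first, then fill small holes.

    A component survives iff its area is >= min_region_fraction * H * W
    ("less than" the threshold is removed, read strictly).  The operation is
    idempotent and never leaves a positive component below the threshold.
    """
    cfg = cfg or SegConfig()
    m = (np.asarray(mask) > 0).astype(np.uint8)
    h, w = m.shape
    thresh = cfg.min_region_fraction * h * w
    conn = 2 if cfg.connectivity == 8 else 1

    out = m.copy()
    lab = _cc_label(out, connectivity=conn)
    for region in range(1, lab.max() + 1):
        sel = lab == region
        if sel.sum() < thresh:
            out[sel] = 0

    neg = 1 - out
    lab = _cc_label(neg, connectivity=conn)
    for region in range(1, lab.max() + 1):
        sel = lab == region
        if sel.sum() < thresh:
            out[sel] = 1
    return out


def segment_image(
    model: LinearModel,
    image: SlideImage,
    extractor: FeatureExtractor,
    cfg: SegConfig | None = None,
    return_decisions: bool = False,
):
    """Full segmentation: dense patch prediction, pixel vote, smoothing."""
    cfg = cfg or SegConfig()
    labels, decisions, grid = predict_patch_labels(model, image, extractor, cfg)
    voted = vote_pixels(grid, labels, image.shape)
    smoothed = smooth_regions(voted, cfg)
    if return_decisions:
        return smoothed, decisions, grid
    return smoothed
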