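"""Image-level classification with an L2-regularized linear SVM.

The image feature is the P-norm pool of its patch features; binary tasks
additionally restrict to the top-k mean-difference components.  The
classifier minimizes the standard hinge-loss objective

    (1/2) w'w + C * sum_i max(0, 1 - y_i w'x_i)

with C chosen from {0.01, 0.1, 1, 10, 100} by stratified cross-validation
on the training data (ties resolved toward the smallest, i.e. most
regularized, C).  Multiclass uses one-vs-rest on the full feature vector:
one binary decision function per class, prediction by maximal decision
value, ties broken by class order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from histopatch.errors import ConfigurationError, EmptyTissueError, InputError
from histopatch.features import FeatureExtractor, extract_features
from histopatch.pooling import (
    DEFAULT_K_SELECT,
    PoolingConfig,
    feature_diff,
    pnorm_pool,
    select_top_k,
)
from histopatch.tiling import SlideImage, TilingConfig, extract_patches, generate_grid

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class TrainConfig:
    """Training-time knobs: the C grid, CV folds, selection size, seed."""

    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    cv_folds: int = 5
    seed: int = 0
    multiclass: str = "one-vs-rest"
    k_select: int | None = DEFAULT_K_SELECT
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.C_grid):
            raise InputError("all C values must be > 0")
        if self.cv_folds < 2:
            raise InputError("cv_folds must be >= 2")


@dataclass
class LinearModel:
    """Trained linear decision functions plus the metadata needed to apply them.

    ``weights`` is (n_decision, D') and ``biases`` (n_decision,); for binary
    models n_decision = 1 and the positive class is ``classes[1]``.
    ``selected_indices`` (binary only) maps the D'-dim weight space back to
    the original feature dimensions.
    """

    classes: list[str]
    weights: np.ndarray
    biases: np.ndarray
    selected_indices: np.ndarray | None = None
    pooling_P: float = 3.0
    extractor_name: str = ""
    C: float = 1.0
    tol: float = 1e-4
    patch_size: int | None = None
    stride: int | None = None
    target_size: int | None = None
    diffs: np.ndarray | None = field(default=None, repr=False)

    # -- application ---------------------------------------------------------

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        """Raw decision values from full-D feature vectors, (n_images, n_decision).

        When the model carries a selection, the restriction (a permutation
        when k = D) is always applied here; callers pass unselected features.
        """
        x = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if self.selected_indices is not None:
            x = x[:, self.selected_indices]
        return x @ self.weights.T + self.biases

    def predict(self, features: np.ndarray) -> list[str]:
        d = self.decision_values(features)
        if len(self.classes) == 2 and d.shape[1] == 1:
            return [self.classes[1] if v > 0 else self.classes[0] for v in d[:, 0]]
        return [self.classes[int(np.argmax(row))] for row in d]

    # -- persistence: JSON metadata + npz weights, bit-exact round trip ------

    def save(self, model_dir) -> None:
        d = Path(model_dir)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "classes": self.classes,
            "pooling_P": self.pooling_P,
            "extractor_name": self.extractor_name,
            "C": self.C,
            "tol": self.tol,
            "patch_size": self.patch_size,
            "stride": self.stride,
            "target_size": self.target_size,
            "has_selection": self.selected_indices is not None,
        }
        (d / "model.json").write_text(json.dumps(meta, indent=1))
        arrays = {"weights": self.weights, "biases": self.biases}
        if self.selected_indices is not None:
            arrays["selected_indices"] = self.selected_indices
        if self.diffs is not None:
            arrays["diffs"] = self.diffs
        np.savez(d / "weights.npz", **arrays)

    @classmethod
    def load(cls, model_dir) -> "LinearModel":
        d = Path(model_dir)
        meta = json.loads((d / "model.json").read_text())
        arrays = np.load(d / "weights.npz")
        return cls(
            classes=meta["classes"],
            weights=arrays["weights"],
            biases=arrays["biases"],
            selected_indices=arrays["selected_indices"] if meta["has_selection"] else None,
            pooling_P=meta["pooling_P"],
            extractor_name=meta["extractor_name"],
            C=meta["C"],
            tol=meta["tol"],
            patch_size=meta["patch_size"],
            stride=meta["stride"],
            target_size=meta["target_size"],
            diffs=arrays["diffs"] if "diffs" in arrays else None,
        )


def image_feature(
    image: SlideImage,
    extractor: FeatureExtractor,
    tiling_cfg: TilingConfig,
    pooling_cfg: PoolingConfig | None = None,
) -> np.ndarray:
    """Tile, background-filter, resize, extract and pool one slide.

    Raises :class:`EmptyTissueError` when every grid patch is background
    (an all-glass slide has no feature).
    """
    grid = generate_grid(image, tiling_cfg)
    patches, kept = extract_patches(image, grid, tiling_cfg)
    if not patches:
        raise EmptyTissueError(
            f"no non-background patches survive tiling (grid had {len(grid)} boxes)"
        )
    feats = extract_features(extractor, patches)
    return pnorm_pool(feats, pooling_cfg or PoolingConfig())


def _fit_svc(x: np.ndarray, y: np.ndarray, C: float, tol: float, seed: int) -> LinearSVC:
    clf = LinearSVC(C=C, loss="hinge", tol=tol, random_state=seed, max_iter=100_000)
    clf.fit(x, y)
    return clf


def _effective_k(cfg: TrainConfig, d: int) -> int | None:
    if cfg.k_select is None:
        return None
    if cfg.k_select > d:
        logger.warning("k_select=%d exceeds feature dimension %d; clamping", cfg.k_select, d)
        return d
    return int(cfg.k_select)


def _binary_selection(x, y_is_pos, k):
    diffs = feature_diff(x[y_is_pos], x[~y_is_pos])
    return select_top_k(diffs, k, n_pos=int(y_is_pos.sum()), n_neg=int((~y_is_pos).sum()))


def select_C(features, labels, cfg: TrainConfig, fit_and_score=None) -> float:
    """Pick C from ``cfg.C_grid`` by stratified k-fold CV on training data.

    Returns the grid value with the highest mean fold accuracy; ties go to
    the smallest C.  When the rarest class has fewer members than
    ``cv_folds``, the fold count is reduced with a warning.  By default each
    fold refits mean-difference selection (binary) before the SVM so the
    selection never sees validation images; ``fit_and_score`` overrides the
    per-fold fit for other pipelines.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    folds = int(min(cfg.cv_folds, counts.min()))
    if folds < cfg.cv_folds:
        logger.warning("reducing cv folds from %d to %d (smallest class)", cfg.cv_folds, folds)
    if folds < 2:
        logger.warning("cannot cross-validate with a class of size 1; returning smallest C")
        return float(min(cfg.C_grid))

    if fit_and_score is None:
        k = _effective_k(cfg, x.shape[1]) if len(classes) == 2 else None

        def fit_and_score(x_tr, y_tr, x_va, y_va, C):
            if k is not None:
                pos = y_tr == classes[1]
                sel = _binary_selection(x_tr, pos, k).selected
                x_tr, x_va = x_tr[:, sel], x_va[:, sel]
            clf = _fit_svc(x_tr, y_tr, C, cfg.tol, cfg.seed)
            return float((clf.predict(x_va) == y_va).mean())

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    splits = list(skf.split(x, y))
    grid = sorted(cfg.C_grid)
    means = []
    for C in grid:
        scores = [fit_and_score(x[tr], y[tr], x[va], y[va], C) for tr, va in splits]
        means.append(float(np.mean(scores)))
    best = int(np.argmax(means))  # argmax takes the first maximum -> smallest C on ties
    logger.info("C grid %s -> mean accuracies %s; chose C=%g", grid, means, grid[best])
    return float(grid[best])


def train_binary(features, labels, cfg: TrainConfig | None = None, **model_meta) -> LinearModel:
    """Fit the binary image classifier: selection, C search, final SVM.

    ``features`` holds one pooled vector per image.  Mean-difference
    selection and the C grid search are both fit strictly within the
    training data.
    """
    cfg = cfg or TrainConfig()
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    classes = sorted(np.unique(y).tolist())
    if len(classes) != 2:
        raise InputError(f"train_binary needs exactly 2 classes, got {classes}")

    chosen_c = select_C(x, y, cfg)
    k = _effective_k(cfg, x.shape[1])
    sel = None
    diffs = None
    x_fit = x
    if k is not None:
        result = _binary_selection(x, y == classes[1], k)
        sel, diffs = result.selected, result.diffs
        x_fit = x[:, sel]
    clf = _fit_svc(x_fit, y, chosen_c, cfg.tol, cfg.seed)
    return LinearModel(
        classes=[str(c) for c in clf.classes_],
        weights=np.asarray(clf.coef_, dtype=np.float64),
        biases=np.asarray(clf.intercept_, dtype=np.float64),
        selected_indices=sel,
        C=chosen_c,
        tol=cfg.tol,
        diffs=diffs,
        **model_meta,
    )


def train_multiclass(features, labels, cfg: TrainConfig | None = None, **model_meta) -> LinearModel:
    """One-vs-rest linear SVMs on the full feature vector (no selection)."""
    cfg = cfg or TrainConfig()
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise InputError("need at least 2 classes")

    def ovr_fit_and_score(x_tr, y_tr, x_va, y_va, C):
        w, b = _ovr_weights(x_tr, y_tr, classes, C, cfg)
        pred = [classes[int(np.argmax(row))] for row in x_va @ w.T + b]
        return float((np.asarray(pred) == y_va).mean())

    chosen_c = select_C(x, y, cfg, fit_and_score=ovr_fit_and_score)
    w, b = _ovr_weights(x, y, classes, chosen_c, cfg)
    return LinearModel(
        classes=[str(c) for c in classes],
        weights=w,
        biases=b,
        selected_indices=None,
        C=chosen_c,
        tol=cfg.tol,
        **model_meta,
    )


def _ovr_weights(x, y, classes, C, cfg: TrainConfig):
    """One decision function per class: class vs rest."""
    ws, bs = [], []
    for c in classes:
        clf = _fit_svc(x, (y == c).astype(int), C, cfg.tol, cfg.seed)
        ws.append(clf.coef_[0])
        bs.append(clf.intercept_[0])
    return np.asarray(ws, dtype=np.float64), np.asarray(bs, dtype=np.float64)


def predict_image(
    model: LinearModel,
    image: SlideImage,
    extractor: FeatureExtractor,
    tiling_cfg: TilingConfig,
) -> tuple[str, np.ndarray]:
    """Classify one slide; returns (label, per-decision raw values).

    The extractor must be the one the model was trained with.
    """
    if model.extractor_name and extractor.name != model.extractor_name:
        raise ConfigurationError(
            f"model was trained with extractor {model.extractor_name!r}, got {extractor.name!r}"
        )
    feat = image_feature(image, extractor, tiling_cfg, PoolingConfig(P=model.pooling_P))
    decisions = model.decision_values(feat[None, :])[0]
    label = model.predict(feat[None, :])[0]
    return label, decisions
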