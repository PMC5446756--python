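"""Patch feature extractors and the fine-tuning recipe.

The pipeline is agnostic to where patch features come from; it only relies
on the extractor contract: a fixed-size RGB patch maps to a length-D vector
of finite, nonnegative values, deterministically.  The reference deep
backbone (an AlexNet-style table of conv/pool layers ending in two
4096-wide fully connected layers, features read off the penultimate one
after rectification) satisfies this because rectified-linear activations
are nonnegative; its pre-trained weights are an optional user-supplied
plug-in and are never downloaded here.

Two extractors ship with the package:

* :func:`reference_extractor` — a deterministic hand-crafted descriptor
  (per-channel intensity histograms plus a gradient-magnitude histogram)
  that needs no training and makes the whole pipeline testable.
* :class:`TinyConvBackbone` — a miniature trainable convolutional network
  (two conv layers, global average pooling, one rectified fully connected
  feature layer, a removable softmax head) used to exercise the
  fine-tuning procedure: replace the classification head with a freshly
  initialized ``head_width``-way layer and continue stochastic gradient
  descent through every layer at a constant learning rate.
"""

from __future__ import annotations

import copy
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from histopatch.errors import InputError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class FeatureExtractor:
    """Callable wrapper mapping one RGB patch to a length-D feature vector.

    ``input_size`` of ``None`` accepts any square RGB patch; otherwise
    patches must be ``input_size x input_size x 3``.
    """

    name: str
    output_dim: int
    fn: Callable[[np.ndarray], np.ndarray]
    deterministic: bool = True
    input_size: int | None = None
    loss_history: list[float] = field(default_factory=list, repr=False)

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        return self.fn(patch)


@dataclass
class BackboneSpec:
    """Layer table of the reference deep backbone (metadata only).

    ``(name, output_dims, kernel, stride)`` per layer; the features used by
    the pipeline are the 4096 activations of the second fully connected
    layer.
    """

    layers: tuple = (
        ("input", (224, 224, 3), None, None),
        ("conv1", (55, 55, 96), 11, 4),
        ("pool1", (27, 27, 96), 3, 2),
        ("conv2", (27, 27, 256), 5, 1),
        ("pool2", (13, 13, 256), 3, 2),
        ("conv3", (13, 13, 384), 3, 1),
        ("conv4", (13, 13, 384), 3, 1),
        ("conv5", (13, 13, 256), 3, 1),
        ("pool3", (6, 6, 256), 3, 2),
        ("fc1", (4096,), None, None),
        ("fc2", (4096,), None, None),
    )

    @property
    def feature_dim(self) -> int:
        return self.layers[-1][1][0]


@dataclass
class FineTuneConfig:
    """Fine-tuning schedule: constant-rate SGD with a replaced head.

    ``learning_rate`` applies to the unmodified layers; the freshly
    initialized head uses ``learning_rate * head_lr_multiplier`` (the
    multiplier defaults to 1, i.e. one uniform rate).
    """

    learning_rate: float = 1e-4
    epochs: int = 20
    head_width: int = 2
    batch_size: int = 32
    head_lr_multiplier: float = 1.0
    lr_schedule: str = "constant"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ParameterError("learning_rate must be >= 0")
        if self.epochs < 0:
            raise ParameterError("epochs must be >= 0")


# ---------------------------------------------------------------------------
# reference extractor: intensity + gradient histograms


def _gradient_magnitude(gray: np.ndarray) -> np.ndarray:
    gy, gx = np.gradient(gray)
    return np.hypot(gx, gy)


def reference_extractor(bins_per_channel: int = 8, texture_stats: int = 8) -> FeatureExtractor:
    """Deterministic histogram descriptor: D = 3*bins_per_channel + texture_stats.

    Per channel, a normalized intensity histogram over [0, 256); appended, a
    normalized histogram of grey-level gradient magnitudes (clipped to
    [0, 64)) as a texture statistic.  All components are nonnegative and
    each histogram block sums to 1 on a nonempty patch.
    """
    if bins_per_channel < 2:
        raise ParameterError("bins_per_channel must be >= 2")
    if texture_stats < 1:
        raise ParameterError("texture_stats must be >= 1")

    def fn(patch: np.ndarray) -> np.ndarray:
        px = np.asarray(patch)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] == 0:
            raise InputError(f"expected nonempty H x W x 3 patch, got shape {px.shape}")
        n = px.shape[0] * px.shape[1]
        pxf = px.astype(np.float64)
        parts = []
        # uniform bins over [0, 256): bucket index = floor(value * bins / 256)
        for c in range(3):
            idx = np.clip(pxf[:, :, c] * (bins_per_channel / 256.0), 0, bins_per_channel - 1)
            hist = np.bincount(idx.astype(np.intp).ravel(), minlength=bins_per_channel)
            parts.append(hist / n)
        gray = 0.299 * pxf[:, :, 0] + 0.587 * pxf[:, :, 1] + 0.114 * pxf[:, :, 2]
        gm = np.clip(_gradient_magnitude(gray), 0.0, 64.0 - 1e-9)
        idx = (gm * (texture_stats / 64.0)).astype(np.intp)
        hist = np.bincount(idx.ravel(), minlength=texture_stats)
        parts.append(hist / n)
        return np.concatenate(parts)

    d = 3 * bins_per_channel + texture_stats
    return FeatureExtractor(
        name=f"reference-hist{bins_per_channel}x{texture_stats}",
        output_dim=d,
        fn=fn,
        deterministic=True,
        input_size=None,
    )


def extract_features(extractor: FeatureExtractor, patches: Sequence[np.ndarray]) -> np.ndarray:
    """Stack per-patch features into an N x D matrix, row order = patch order.

    Wrong-size patches raise :class:`InputError`; non-finite extractor
    output raises :class:`InputError` (extractor fault); negative outputs
    are clamped to 0 with a warning so third-party backbones whose feature
    layer is not rectified remain usable.
    """
    rows = []
    for i, patch in enumerate(patches):
        px = np.asarray(patch)
        if extractor.input_size is not None and (
            px.shape[0] != extractor.input_size or px.shape[1] != extractor.input_size
        ):
            raise InputError(
                f"patch {i} has size {px.shape[:2]}, extractor {extractor.name!r} "
                f"expects {extractor.input_size}"
            )
        v = np.asarray(extractor(px), dtype=np.float64).ravel()
        if v.shape[0] != extractor.output_dim:
            raise InputError(
                f"extractor {extractor.name!r} returned {v.shape[0]} values, declared "
                f"output_dim={extractor.output_dim}"
            )
        if not np.all(np.isfinite(v)):
            raise InputError(f"extractor {extractor.name!r} returned non-finite values")
        if (v < 0).any():
            warnings.warn(
                f"extractor {extractor.name!r} returned negative components; clamping to 0",
                stacklevel=2,
            )
            v = np.maximum(v, 0.0)
        rows.append(v)
    return np.asarray(rows, dtype=np.float64).reshape(len(rows), extractor.output_dim)


# ---------------------------------------------------------------------------
# miniature trainable backbone (pure numpy)


def _conv_indices(c: int, h: int, w: int, k: int, stride: int, pad: int):
    out_h = (h + 2 * pad - k) // stride + 1
    out_w = (w + 2 * pad - k) // stride + 1
    i0 = np.tile(np.repeat(np.arange(k), k), c)
    j0 = np.tile(np.arange(k), k * c)
    i1 = stride * np.repeat(np.arange(out_h), out_w)
    j1 = stride * np.tile(np.arange(out_w), out_h)
    i = i0.reshape(-1, 1) + i1.reshape(1, -1)
    j = j0.reshape(-1, 1) + j1.reshape(1, -1)
    ch = np.repeat(np.arange(c), k * k).reshape(-1, 1)
    return ch, i, j, out_h, out_w


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ch, i, j, out_h, out_w = _conv_indices(c, h, w, k, stride, pad)
    cols = xp[:, ch, i, j]  # (N, C*k*k, L)
    return cols, (ch, i, j, out_h, out_w, h, w)


def _col2im(dcols: np.ndarray, meta, n: int, c: int, pad: int) -> np.ndarray:
    ch, i, j, _, _, h, w = meta
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    np.add.at(dxp, (np.arange(n)[:, None, None], ch, i, j), dcols)
    return dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp


class _Conv:
    def __init__(self, rng, c_in, c_out, k=3, stride=2, pad=1):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x):
        cols, meta = _im2col(x, self.k, self.stride, self.pad)
        self._cols, self._meta, self._x_shape = cols, meta, x.shape
        wf = self.w.reshape(self.w.shape[0], -1)
        out = np.einsum("ok,nkl->nol", wf, cols) + self.b[None, :, None]
        n = x.shape[0]
        return out.reshape(n, self.w.shape[0], meta[3], meta[4])

    def backward(self, dout):
        n, c_out, oh, ow = dout.shape
        dflat = dout.reshape(n, c_out, oh * ow)
        self.dw = np.einsum("nol,nkl->ok", dflat, self._cols).reshape(self.w.shape)
        self.db = dflat.sum(axis=(0, 2))
        wf = self.w.reshape(c_out, -1)
        dcols = np.einsum("ok,nol->nkl", wf, dflat)
        return _col2im(dcols, self._meta, n, self._x_shape[1], self.pad)


class _Linear:
    def __init__(self, rng, d_in, d_out):
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T


class TinyConvBackbone:
    """Two-conv numpy network with a removable softmax classification head.

    Layout: conv(3->c1, k3 s2) - ReLU - conv(c1->c2, k3 s2) - ReLU - global
    average pool - fc(c2->feature_dim) - ReLU = features; head
    fc(feature_dim->n_classes) for training.  Features are nonnegative by
    construction (they follow a rectifier), matching the extractor contract.
    """

    def __init__(
        self,
        input_size: int = 32,
        channels: tuple[int, int] = (8, 16),
        feature_dim: int = 16,
        n_classes: int = 2,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.feature_dim = feature_dim
        self.conv1 = _Conv(rng, 3, channels[0])
        self.conv2 = _Conv(rng, channels[0], channels[1])
        self.fc = _Linear(rng, channels[1], feature_dim)
        self.head = _Linear(rng, feature_dim, n_classes)

    # -- forward passes -----------------------------------------------------

    def _prep(self, patches: Sequence[np.ndarray]) -> np.ndarray:
        x = np.asarray(patches, dtype=np.float64) / 255.0  # (N, H, W, 3)
        if x.ndim != 4 or x.shape[1] != self.input_size or x.shape[2] != self.input_size:
            raise InputError(
                f"backbone expects {self.input_size}x{self.input_size} RGB patches, got {x.shape}"
            )
        return x.transpose(0, 3, 1, 2)

    def features(self, patches: Sequence[np.ndarray]) -> np.ndarray:
        """Rectified feature-layer activations, (N, feature_dim)."""
        x = self._prep(patches)
        a1 = np.maximum(self.conv1.forward(x), 0.0)
        a2 = np.maximum(self.conv2.forward(a1), 0.0)
        pooled = a2.mean(axis=(2, 3))
        return np.maximum(self.fc.forward(pooled), 0.0)

    def _forward_train(self, x):
        z1 = self.conv1.forward(x)
        a1 = np.maximum(z1, 0.0)
        z2 = self.conv2.forward(a1)
        a2 = np.maximum(z2, 0.0)
        pooled = a2.mean(axis=(2, 3))
        zf = self.fc.forward(pooled)
        af = np.maximum(zf, 0.0)
        logits = self.head.forward(af)
        cache = (z1, z2, a2.shape, zf)
        return logits, cache

    def _backward(self, dlogits, cache):
        z1, z2, a2_shape, zf = cache
        daf = self.head.backward(dlogits)
        dzf = daf * (zf > 0)
        dpooled = self.fc.backward(dzf)
        n, c2, oh, ow = a2_shape
        da2 = np.broadcast_to(dpooled[:, :, None, None] / (oh * ow), a2_shape)
        dz2 = da2 * (z2 > 0)
        da1 = self.conv2.backward(dz2)
        dz1 = da1 * (z1 > 0)
        self.conv1.backward(dz1)

    # -- training -----------------------------------------------------------

    def replace_head(self, n_classes: int, rng: np.random.Generator) -> None:
        self.head = _Linear(rng, self.feature_dim, n_classes)

    def loss(self, patches, y: np.ndarray) -> float:
        logits, _ = self._forward_train(self._prep(patches))
        return float(_softmax_ce(logits, y)[0])

    def train_step(self, x: np.ndarray, y: np.ndarray, lr: float, head_lr: float) -> float:
        logits, cache = self._forward_train(x)
        loss, dlogits = _softmax_ce(logits, y)
        self._backward(dlogits, cache)
        for layer, rate in ((self.conv1, lr), (self.conv2, lr), (self.fc, lr), (self.head, head_lr)):
            layer.w -= rate * layer.dw
            layer.b -= rate * layer.db
        return float(loss)

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            "conv1.w": self.conv1.w, "conv1.b": self.conv1.b,
            "conv2.w": self.conv2.w, "conv2.b": self.conv2.b,
            "fc.w": self.fc.w, "fc.b": self.fc.b,
            "head.w": self.head.w, "head.b": self.head.b,
        }

    def as_extractor(self, name: str = "tinyconv") -> FeatureExtractor:
        return FeatureExtractor(
            name=name,
            output_dim=self.feature_dim,
            fn=lambda patch: self.features([patch])[0],
            deterministic=True,
            input_size=self.input_size,
        )


def _softmax_ce(logits: np.ndarray, y: np.ndarray):
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(p[np.arange(n), y] + 1e-300).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


def fine_tune_backbone(
    backbone: TinyConvBackbone,
    labeled_patches: Sequence[tuple[np.ndarray, object]],
    cfg: FineTuneConfig,
) -> FeatureExtractor:
    """Fine-tune a trainable backbone on labeled patches.

    The classification head is replaced by a freshly initialized
    ``cfg.head_width``-way layer, then all layers are updated by minibatch
    stochastic gradient descent at constant ``cfg.learning_rate`` for
    ``cfg.epochs`` epochs (the head at ``learning_rate * head_lr_multiplier``).
    The head is then discarded and the rectified feature-layer activations
    are exposed through the returned extractor, whose ``loss_history`` holds
    the full-dataset loss at the end of each epoch.

    ``epochs == 0`` leaves features identical to the input backbone's, and
    ``learning_rate == 0`` leaves every parameter bit-unchanged.
    """
    net = copy.deepcopy(backbone)
    rng = np.random.default_rng(cfg.seed)

    patches = [p for p, _ in labeled_patches]
    raw_labels = [lab for _, lab in labeled_patches]
    classes = sorted(set(raw_labels), key=str)
    if len(classes) > cfg.head_width:
        raise ParameterError(
            f"{len(classes)} classes present but head_width={cfg.head_width}"
        )
    y = np.array([classes.index(lab) for lab in raw_labels])
    net.replace_head(cfg.head_width, rng)

    x_all = net._prep(patches)
    n = x_all.shape[0]
    history: list[float] = []
    head_lr = cfg.learning_rate * cfg.head_lr_multiplier
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            net.train_step(x_all[sel], y[sel], cfg.learning_rate, head_lr)
        history.append(net.loss(patches, y))

    ext = net.as_extractor(name="finetuned-tinyconv")
    ext.loss_history = history
    ext._net = net  # keep the trained network reachable for inspection
    return ext


# ---------------------------------------------------------------------------
# feature-matrix persistence: .npy array + JSON sidecar, bit-exact round trip


def save_features(matrix: np.ndarray, path_prefix, extractor_name: str, boxes=None) -> None:
    prefix = Path(path_prefix)
    np.save(prefix.with_suffix(".npy"), np.asarray(matrix, dtype=np.float64))
    sidecar = {
        "extractor": extractor_name,
        "n": int(matrix.shape[0]),
        "d": int(matrix.shape[1]),
        "boxes": [list(map(int, b)) for b in boxes] if boxes is not None else None,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_features(path_prefix) -> tuple[np.ndarray, dict]:
    prefix = Path(path_prefix)
    matrix = np.load(prefix.with_suffix(".npy"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return matrix, meta
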