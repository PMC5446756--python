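"""JSON run configuration, defaults, and the end-to-end pipeline runner.

A run is described by one JSON object; omitted keys take the framework
defaults (P = 3, stride 64 for classification and 8 for segmentation, patch
336/672/112, background threshold 200, k = 100, C grid
{0.01, 0.1, 1, 10, 100}, overlap threshold 0.6, 5% smoothing).  Unknown keys
are rejected with the offending key path, and the fully populated effective
configuration is echoed into every output directory so reruns are
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from histopatch.classify import (
    LinearModel,
    TrainConfig,
    image_feature,
    train_binary,
    train_multiclass,
)
from histopatch.errors import ConfigurationError
from histopatch.evaluate import classification_accuracy, score_masks
from histopatch.features import FeatureExtractor, TinyConvBackbone, reference_extractor
from histopatch.pooling import PoolingConfig
from histopatch.segment import SegConfig, segment_image, train_patch_classifier
from histopatch.synthdata import load_mask, save_mask
from histopatch.tiling import SlideImage, TilingConfig


@dataclass
class ExtractorSpec:
    """Which feature extractor to build, with its parameters."""

    name: str = "reference"
    bins_per_channel: int = 8
    texture_stats: int = 8
    feature_dim: int = 16
    input_size: int = 32

    def build(self, seed: int = 0) -> FeatureExtractor:
        if self.name == "reference":
            return reference_extractor(self.bins_per_channel, self.texture_stats)
        if self.name == "tinyconv":
            return TinyConvBackbone(
                input_size=self.input_size, feature_dim=self.feature_dim, seed=seed
            ).as_extractor()
        raise ConfigurationError(f"unknown extractor {self.name!r}")


@dataclass
class RunConfig:
    """Everything a run needs: task, per-stage configs, extractor, seed, output."""

    task: str = "classification"
    tiling: TilingConfig = field(default_factory=TilingConfig)
    pooling: PoolingConfig = field(default_factory=PoolingConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    segmentation: SegConfig = field(default_factory=SegConfig)
    extractor: ExtractorSpec = field(default_factory=ExtractorSpec)
    seed: int = 0
    output_dir: str = "run_output"

    def __post_init__(self) -> None:
        if self.task not in ("classification", "segmentation"):
            raise ConfigurationError(f"task must be classification or segmentation, got {self.task!r}")


def _build_dataclass(cls, data: dict, path: str):
    """Instantiate a dataclass from a dict, rejecting unknown keys by path."""
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path or 'config'}: expected an object, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        where = f"{path}.{key}" if path else key
        if key not in fields:
            raise ConfigurationError(f"unknown configuration key: {where!r}")
        ftype = fields[key].type
        if dataclasses.is_dataclass(_resolve(ftype)):
            kwargs[key] = _build_dataclass(_resolve(ftype), value, where)
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"{path or 'config'}: {exc}") from exc


_KNOWN = {
    "TilingConfig": TilingConfig,
    "PoolingConfig": PoolingConfig,
    "TrainConfig": TrainConfig,
    "SegConfig": SegConfig,
    "ExtractorSpec": ExtractorSpec,
}


def _resolve(ftype):
    if isinstance(ftype, str):
        return _KNOWN.get(ftype, str)
    return ftype


def load_config(path) -> RunConfig:
    """Parse a JSON run configuration, applying defaults for omitted keys."""
    data = json.loads(Path(path).read_text())
    return config_from_dict(data)


def config_from_dict(data: dict) -> RunConfig:
    return _build_dataclass(RunConfig, data, "")


def config_to_dict(cfg: RunConfig) -> dict:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        return o

    return json.loads(json.dumps(dataclasses.asdict(cfg), default=default))


def _run_metadata(cfg: RunConfig) -> dict:
    import sklearn
    import skimage

    import histopatch

    return {
        "config": config_to_dict(cfg),
        "seed": cfg.seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "versions": {
            "python": platform.python_version(),
            "histopatch": histopatch.__version__,
            "numpy": np.__version__,
            "scikit-learn": sklearn.__version__,
            "scikit-image": skimage.__version__,
        },
    }


def _load_manifest(manifest_path) -> tuple[pd.DataFrame, Path]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    if "image_path" not in df.columns:
        raise ConfigurationError("manifest must have an image_path column")
    return df, manifest_path.parent


def run_pipeline(cfg: RunConfig, manifest_path) -> Path:
    """Train on a manifest and write model, predictions and reports.

    Classification manifests need ``image_path,label`` columns; segmentation
    manifests need ``image_path,mask_path``.  Returns the output directory.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_metadata.json").write_text(json.dumps(_run_metadata(cfg), indent=1))
    (out / "config.json").write_text(json.dumps(config_to_dict(cfg), indent=1))

    df, root = _load_manifest(manifest_path)
    extractor = cfg.extractor.build(cfg.seed)
    training = dataclasses.replace(cfg.training, seed=cfg.seed)

    if cfg.task == "classification":
        images = [SlideImage.open(root / p) for p in df["image_path"]]
        labels = df["label"].astype(str).tolist()
        feats = np.vstack(
            [image_feature(img, extractor, cfg.tiling, cfg.pooling) for img in images]
        )
        n_classes = len(set(labels))
        train = train_binary if n_classes == 2 else train_multiclass
        model = train(
            feats,
            labels,
            training,
            pooling_P=cfg.pooling.P,
            extractor_name=extractor.name,
            patch_size=cfg.tiling.patch_size,
            stride=cfg.tiling.stride,
            target_size=cfg.tiling.target_size,
        )
        model.save(out / "model")
        decisions = model.decision_values(feats)
        preds = model.predict(feats)
        report = pd.DataFrame({"image_path": df["image_path"], "predicted_label": preds})
        dec_cols = model.classes if decisions.shape[1] > 1 else [model.classes[1]]
        for j, cname in enumerate(dec_cols):
            report[f"decision_{cname}"] = decisions[:, j]
        report.to_csv(out / "predictions.csv", index=False)
        summary = {
            "task": "classification",
            "n_images": len(images),
            "classes": model.classes,
            "C": model.C,
            "training_accuracy": classification_accuracy(preds, labels),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        return out

    # segmentation
    if "mask_path" not in df.columns:
        raise ConfigurationError("segmentation manifest must have a mask_path column")
    records = [
        {"image": SlideImage.open(root / r.image_path), "mask": load_mask(root / r.mask_path)}
        for r in df.itertuples()
    ]
    seg_train_cfg = dataclasses.replace(training, k_select=None)
    model = train_patch_classifier(records, extractor, cfg.segmentation, seg_train_cfg)
    model.save(out / "model")
    (out / "masks").mkdir(exist_ok=True)
    preds, truths = [], []
    for r, rec in zip(df.itertuples(), records):
        mask = segment_image(model, rec["image"], extractor, cfg.segmentation)
        save_mask(mask, out / "masks" / Path(r.image_path).name)
        preds.append(mask)
        truths.append(rec["mask"])
    report = score_masks(preds, truths)
    pd.DataFrame(
        {"image_path": df["image_path"], "score": report.per_image_scores}
    ).to_csv(out / "scores.csv", index=False)
    summary = {
        "task": "segmentation",
        "n_images": report.K,
        "C": model.C,
        "mean_score": report.mean_score,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return out
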