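"""Seeded generator of synthetic H&E-like slides, labels and masks.

Real whole-slide images are gigapixel-scale and not redistributable, so
every pipeline stage here is exercised on small synthetic slides that keep
the features the method depends on: a bright glass border (all channels
above the background threshold), a pink tissue field with scattered dark
nuclei, and — on positive slides — one contiguous "tumor" region whose
nuclei are denser, darker and size-jittered.  The nuclear-density and color
cues are what separate the classes, mirroring the cue the patch features
exploit in real H&E material; no claim of photorealism is made.

All outputs are pure functions of :class:`SynthParams`: the same parameters
(including seed) give byte-identical images and masks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import ellipse as _ellipse
from skimage.draw import polygon as _polygon

from histopatch.errors import ParameterError
from histopatch.tiling import SlideImage

# Per-texture rendering constants.  Field colors are chosen so tissue is
# never all-channels > 200 (it must survive background filtering), while
# class means differ by far more than the default pixel noise so the
# classes are linearly separable from intensity statistics.
_FIELD_COLOR = {
    "normal": (232, 168, 205),
    "tumor": (198, 122, 168),
    "stroma": (238, 188, 186),
    "background": (242, 242, 242),
}
_NUCLEUS_COLOR = {
    "normal": (96, 48, 128),
    "tumor": (52, 26, 88),
    "stroma": (150, 96, 140),
}
_BLOB_DENSITY = {"normal": 1.2, "tumor": 6.0, "stroma": 0.4}  # nuclei per 1e4 px^2
_RADIUS_RANGE = {"normal": (4, 7), "tumor": (3, 9), "stroma": (2, 4)}


@dataclass
class SynthParams:
    """Parameters of the synthetic slide generator.

    ``tumor_fraction`` is the target tumor area as a fraction of the tissue
    area (the image minus the white border).  ``texture_classes`` lists the
    tissue textures available to dataset builders; "background" refers to
    the glass border and is always rendered.
    """

    image_height: int = 512
    image_width: int = 512
    texture_classes: tuple[str, ...] = ("normal", "tumor")
    blob_density_per_class: dict[str, float] = field(default_factory=lambda: dict(_BLOB_DENSITY))
    blob_radius_range_per_class: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_RADIUS_RANGE)
    )
    color_mean_per_class: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(_FIELD_COLOR)
    )
    color_noise_sd: float = 8.0
    tumor_fraction: float = 0.3
    border_px: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 1 or self.image_width < 1:
            raise ParameterError("image dimensions must be >= 1")
        if not (0.0 <= self.tumor_fraction <= 1.0):
            raise ParameterError("tumor_fraction must lie in [0, 1]")
        for name, (lo, hi) in self.blob_radius_range_per_class.items():
            if lo > hi:
                raise ParameterError(f"radius range for {name!r} has min > max")


def _noise_field(rng: np.random.Generator, shape, mean, sd) -> np.ndarray:
    base = np.asarray(mean, dtype=np.float64)
    out = base + rng.normal(0.0, sd, size=(*shape, 3))
    return out


def _scatter_nuclei(
    rng: np.random.Generator,
    canvas: np.ndarray,
    region_mask: np.ndarray,
    texture: str,
    params: SynthParams,
) -> None:
    """Draw randomly oriented dark ellipses at the texture's density inside a region."""
    area = int(region_mask.sum())
    if area == 0:
        return
    density = params.blob_density_per_class.get(texture, _BLOB_DENSITY.get(texture, 1.0))
    r_lo, r_hi = params.blob_radius_range_per_class.get(texture, _RADIUS_RANGE[texture])
    n = int(round(density * area / 1e4))
    if n == 0:
        return
    ys, xs = np.nonzero(region_mask)
    idx = rng.integers(0, len(ys), size=n)
    color = np.asarray(_NUCLEUS_COLOR[texture], dtype=np.float64)
    h, w = canvas.shape[:2]
    for cy, cx in zip(ys[idx], xs[idx]):
        ry = rng.uniform(r_lo, r_hi)
        rx = rng.uniform(r_lo, r_hi)
        rot = rng.uniform(0.0, np.pi)
        rr, cc = _ellipse(cy, cx, ry, rx, shape=(h, w), rotation=rot)
        jitter = rng.normal(0.0, params.color_noise_sd, size=3)
        canvas[rr, cc] = color + jitter


def _tumor_blob_mask(
    rng: np.random.Generator, h: int, w: int, margin: int, target_area: float
) -> np.ndarray:
    """One simply connected smoothed random polygon of roughly the target area."""
    n_angles = 72
    theta = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    # low-order Fourier perturbation of the radius -> smooth, star-convex blob
    wobble = np.zeros(n_angles)
    for k in (2, 3, 5):
        wobble += rng.normal(0.0, 1.0) * np.cos(k * theta) + rng.normal(0.0, 1.0) * np.sin(
            k * theta
        )
    wobble *= 0.12 / max(np.abs(wobble).max(), 1e-9)
    r0 = float(np.sqrt(target_area / np.pi))
    r_max = r0 * 1.15

    lo_y, hi_y = margin + r_max, h - margin - r_max
    lo_x, hi_x = margin + r_max, w - margin - r_max
    if hi_y <= lo_y or hi_x <= lo_x:  # tissue too small for a fully interior blob
        cy, cx = h / 2.0, w / 2.0
    else:
        cy = rng.uniform(lo_y, hi_y)
        cx = rng.uniform(lo_x, hi_x)

    mask = np.zeros((h, w), dtype=np.uint8)
    radii = r0 * (1.0 + wobble)
    rr, cc = _polygon(cy + radii * np.sin(theta), cx + radii * np.cos(theta), shape=(h, w))
    mask[rr, cc] = 1
    # one corrective redraw so the realized area tracks the target
    realized = mask.sum()
    if realized > 0:
        scale = np.sqrt(target_area / realized)
        mask[:] = 0
        rr, cc = _polygon(
            cy + scale * radii * np.sin(theta), cx + scale * radii * np.cos(theta), shape=(h, w)
        )
        mask[rr, cc] = 1
    # keep the blob off the white border
    mask[:margin, :] = 0
    mask[h - margin :, :] = 0
    mask[:, :margin] = 0
    mask[:, w - margin :] = 0
    return mask


def make_slide(
    params: SynthParams, tissue_texture: str = "normal"
) -> tuple[SlideImage, np.ndarray, str]:
    """Generate one synthetic slide.

    Returns the RGB slide, a binary tumor mask (1 = tumor pixel) and the
    class label: ``"tumor"`` iff the tumor area is positive, otherwise the
    tissue texture name.  A tumor region is drawn only when
    ``params.tumor_fraction > 0`` and the tissue texture is ``"normal"``.
    """
    rng = np.random.default_rng(params.seed)
    h, w, m = params.image_height, params.image_width, params.border_px

    # glass border: every channel strictly above the 200 background threshold
    bg_mean = params.color_mean_per_class.get("background", _FIELD_COLOR["background"])
    canvas = _noise_field(rng, (h, w), bg_mean, params.color_noise_sd / 2.0)
    canvas = np.clip(canvas, 206.0, 255.0)

    tissue = np.zeros((h, w), dtype=bool)
    tissue[m : h - m, m : w - m] = True
    field_mean = params.color_mean_per_class.get(tissue_texture, _FIELD_COLOR[tissue_texture])
    tissue_px = _noise_field(rng, (int(tissue.sum()),), field_mean, params.color_noise_sd)
    canvas[tissue] = tissue_px.reshape(-1, 3)

    mask = np.zeros((h, w), dtype=np.uint8)
    if params.tumor_fraction > 0 and tissue_texture == "normal" and tissue.any():
        target = params.tumor_fraction * tissue.sum()
        mask = _tumor_blob_mask(rng, h, w, m, target)
        tumor_mean = params.color_mean_per_class.get("tumor", _FIELD_COLOR["tumor"])
        sel = mask.astype(bool)
        canvas[sel] = _noise_field(rng, (int(sel.sum()),), tumor_mean, params.color_noise_sd).reshape(
            -1, 3
        )

    _scatter_nuclei(rng, canvas, tissue & ~mask.astype(bool), tissue_texture, params)
    if mask.any():
        _scatter_nuclei(rng, canvas, mask.astype(bool), "tumor", params)

    # re-assert the glass border after nuclei (ellipses are clipped to the
    # canvas, not the tissue rectangle)
    border = ~tissue
    canvas[border] = np.clip(canvas[border], 206.0, 255.0)

    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    label = "tumor" if mask.any() else tissue_texture
    return SlideImage(pixels), mask, label


def _derived_params(params: SynthParams, *keys: int, **overrides) -> SynthParams:
    """Child params with a seed derived deterministically from (seed, *keys)."""
    ss = np.random.SeedSequence([int(params.seed), *[int(k) for k in keys]])
    child_seed = int(ss.generate_state(1, dtype=np.uint32)[0])
    return dataclasses.replace(params, seed=child_seed, **overrides)


def make_classification_dataset(
    n_per_class: int, params: SynthParams
) -> list[dict]:
    """Balanced labeled slides, one list entry per image.

    Classes are ``params.texture_classes`` minus "background".  Each record
    is ``{"image": SlideImage, "mask": ndarray, "label": str}``.  Per-image
    seeds are derived from ``params.seed`` and the (class, index) pair, so
    the manifest is reproducible and no two images are identical.
    """
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")
    classes = [c for c in params.texture_classes if c != "background"]
    if "tumor" in classes and params.tumor_fraction <= 0:
        raise ParameterError('class "tumor" requested but tumor_fraction is 0')
    records = []
    for ci, cls in enumerate(classes):
        for i in range(n_per_class):
            if cls == "tumor":
                p = _derived_params(params, ci, i)
                image, mask, label = make_slide(p, tissue_texture="normal")
            else:
                p = _derived_params(params, ci, i, tumor_fraction=0.0)
                image, mask, label = make_slide(p, tissue_texture=cls)
            assert label == cls
            records.append({"image": image, "mask": mask, "label": label})
    return records


def make_segmentation_dataset(n: int, params: SynthParams) -> list[dict]:
    """``n`` positive slides with paired ground-truth masks.

    Every mask is nonempty and not full-frame (the white border is never
    tumor).  Records are ``{"image": SlideImage, "mask": ndarray}``.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if params.tumor_fraction <= 0:
        raise ParameterError("segmentation slides need tumor_fraction > 0")
    records = []
    for i in range(n):
        p = _derived_params(params, 7919, i)
        image, mask, _ = make_slide(p, tissue_texture="normal")
        records.append({"image": image, "mask": mask})
    return records


# ---------------------------------------------------------------------------
# disk I/O: 8-bit RGB PNG images, {0,255} single-channel PNG masks, CSV manifests


def save_mask(mask: np.ndarray, path) -> None:
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255, mode="L").save(path)


def load_mask(path) -> np.ndarray:
    return (np.asarray(Image.open(path).convert("L")) > 127).astype(np.uint8)


def write_classification_dataset(n_per_class: int, params: SynthParams, out_dir) -> Path:
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(make_classification_dataset(n_per_class, params)):
        rel = f"images/slide_{i:03d}.png"
        rec["image"].save(out / rel)
        rows.append({"image_path": rel, "label": rec["label"]})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def write_segmentation_dataset(n: int, params: SynthParams, out_dir) -> Path:
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(make_segmentation_dataset(n, params)):
        rel_img = f"images/slide_{i:03d}.png"
        rel_mask = f"masks/slide_{i:03d}.png"
        rec["image"].save(out / rel_img)
        save_mask(rec["mask"], out / rel_mask)
        rows.append({"image_path": rel_img, "label": "tumor", "mask_path": rel_mask})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
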