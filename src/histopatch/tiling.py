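"""Grid patch sampling, background rejection, and patch resizing.

Whole-slide images are far too large to featurize at once, so they are
divided into overlapping square patches on a rectangular grid.  Patches
whose pixels are all brighter than a background threshold (glass, no
tissue) are discarded; survivors are resized to the feature extractor's
input size.

Coordinates are 0-based and half-open throughout the package: the box with
top-left corner ``(x0, y0)`` and size ``s`` covers pixels
``[x0, x0+s) x [y0, y0+s)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

from histopatch.errors import ConfigurationError, InputError

# Patch-size defaults, by task and source magnification.  At 20x
# (502 nm/pixel) a classification patch is 336 px; at 40x (226 nm/pixel)
# the same physical footprint needs 672 px.  Segmentation uses 112 px
# patches at an 8 px stride regardless of magnification.
_CLS_PATCH = {"20x": 336, "40x": 672}
_SEG_PATCH = 112

CLASSIFICATION_STRIDE = 64
SEGMENTATION_STRIDE = 8
BACKGROUND_THRESHOLD = 200
TARGET_SIZE = 224


@dataclass
class SlideImage:
    """An RGB raster with physical-resolution metadata.

    Parameters
    ----------
    pixels
        H x W x 3 uint8 array.
    resolution_nm_per_px
        Physical scale of one pixel in nanometres (e.g. 502 at 20x,
        226 at 40x).
    magnification
        Source-lens tag: ``"20x"``, ``"40x"`` or ``"other"``.
    """

    pixels: np.ndarray
    resolution_nm_per_px: float = 226.0
    magnification: str = "40x"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise InputError(f"slide pixels must be H x W x 3, got shape {px.shape}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    @classmethod
    def open(cls, path, resolution_nm_per_px: float = 226.0, magnification: str = "40x") -> "SlideImage":
        arr = np.asarray(Image.open(path).convert("RGB"))
        return cls(arr, resolution_nm_per_px, magnification)

    def save(self, path) -> None:
        Image.fromarray(self.pixels.astype(np.uint8), mode="RGB").save(path)


@dataclass
class TilingConfig:
    """Grid sampling parameters.

    ``patch_size`` and ``stride`` are in source pixels; ``target_size`` is
    the side length every kept patch is resized to before feature
    extraction.  A patch counts as background when *every* pixel has all
    three channels strictly greater than ``background_threshold``.
    """

    patch_size: int = 336
    stride: int = CLASSIFICATION_STRIDE
    background_threshold: int = BACKGROUND_THRESHOLD
    target_size: int = TARGET_SIZE

    def __post_init__(self) -> None:
        if self.patch_size < 1 or self.stride < 1 or self.target_size < 1:
            raise InputError("patch_size, stride and target_size must all be >= 1")


@dataclass
class PatchGrid:
    """Row-major list of top-left box corners sharing one patch size."""

    boxes: list[tuple[int, int]] = field(default_factory=list)
    patch_size: int = 336

    def __len__(self) -> int:
        return len(self.boxes)

    def __iter__(self):
        return iter(self.boxes)


def default_patch_size(magnification: str, task: str) -> int:
    """Return the standard patch side length for a magnification and task.

    Classification: 336 px at 20x, 672 px at 40x (equal physical
    footprints).  Segmentation: 112 px at any magnification.  An
    unrecognized magnification for classification must be resolved by an
    explicit user override and raises :class:`ConfigurationError`.
    """
    if task == "segmentation":
        return _SEG_PATCH
    if task != "classification":
        raise ConfigurationError(f"unknown task {task!r}")
    try:
        return _CLS_PATCH[magnification]
    except KeyError:
        raise ConfigurationError(
            f"no default classification patch size for magnification {magnification!r}; "
            "pass patch_size explicitly"
        ) from None


def patch_footprint_nm(patch_size_px: int, resolution_nm_per_px: float) -> float:
    """Physical side length of a patch in nanometres."""
    return patch_size_px * resolution_nm_per_px


def generate_grid(image: SlideImage, cfg: TilingConfig) -> PatchGrid:
    """Enumerate all fully-inside grid boxes, row-major.

    Corners lie at multiples of ``cfg.stride`` starting from (0, 0); a box
    is kept only when it fits entirely inside the image, so right/bottom
    margins narrower than ``patch_size`` are not covered.  The grid may be
    empty when the image is smaller than one patch.
    """
    h, w = image.shape
    s = cfg.patch_size
    xs = range(0, w - s + 1, cfg.stride) if w >= s else range(0)
    ys = range(0, h - s + 1, cfg.stride) if h >= s else range(0)
    boxes = [(x0, y0) for y0 in ys for x0 in xs]
    return PatchGrid(boxes=boxes, patch_size=s)


def is_background(patch_pixels: np.ndarray, threshold: int = BACKGROUND_THRESHOLD) -> bool:
    """True iff every pixel's R, G and B are strictly greater than ``threshold``."""
    px = np.asarray(patch_pixels)
    if px.size == 0:
        raise InputError("empty patch")
    return bool((px > threshold).all())


def resize_patch(patch: np.ndarray, target_size: int) -> np.ndarray:
    """Bilinear resize to ``target_size`` square; exact identity when sizes match."""
    patch = np.asarray(patch)
    if patch.shape[0] == target_size and patch.shape[1] == target_size:
        return patch.copy()
    if patch.dtype == np.uint8 and patch.ndim == 3 and patch.shape[2] == 3:
        pil = Image.fromarray(patch, mode="RGB")
        return np.asarray(pil.resize((target_size, target_size), Image.BILINEAR))
    out = _sk_resize(
        patch.astype(np.float64),
        (target_size, target_size, patch.shape[2]),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.rint(out).clip(0, 255).astype(np.uint8)


def crop(image: SlideImage, box: tuple[int, int], patch_size: int) -> np.ndarray:
    x0, y0 = box
    return image.pixels[y0 : y0 + patch_size, x0 : x0 + patch_size]


def extract_patches(
    image: SlideImage, grid: PatchGrid, cfg: TilingConfig
) -> tuple[list[np.ndarray], list[int]]:
    """Crop, background-filter and resize grid boxes.

    Returns the resized non-background patches and the indices (into the
    original grid order) of the boxes they came from.  Together with the
    rejected boxes this partitions the grid; no box is lost.
    """
    patches: list[np.ndarray] = []
    kept: list[int] = []
    for i, box in enumerate(grid.boxes):
        raw = crop(image, box, grid.patch_size)
        if is_background(raw, cfg.background_threshold):
            continue
        patches.append(resize_patch(raw, cfg.target_size))
        kept.append(i)
    return patches, kept
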