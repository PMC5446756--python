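"""Confidence heatmaps and top-activating-patch galleries.

A heatmap assigns every pixel the mean decision value of the patches
covering it (red = confidently positive, blue = negative, grey = no
coverage), showing which regions drive an image's classification.  The
gallery view inspects individual feature dimensions: the dimensions with
the largest positive classifier weights are taken as the most
class-relevant "neurons", and for each the patches with the highest value
in that dimension are listed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from PIL import Image

from histopatch.classify import LinearModel
from histopatch.errors import InputError, ParameterError
from histopatch.tiling import PatchGrid

NODATA_GREY = (128, 128, 128)


@dataclass
class Heatmap:
    """Per-pixel mean patch confidence; NaN where no patch covers the pixel."""

    values: np.ndarray
    coverage: np.ndarray

    @property
    def nodata(self) -> np.ndarray:
        return self.coverage == 0


def build_heatmap(grid: PatchGrid, decision_values, image_shape: tuple[int, int]) -> Heatmap:
    """Accumulate per-pixel means of covering boxes' decision values.

    Uses 2-D difference arrays for the value sum and the coverage count, so
    cost is O(boxes + pixels).
    """
    vals = np.asarray(decision_values, dtype=np.float64)
    if vals.shape[0] != len(grid.boxes):
        raise InputError("decision_values length does not match grid")
    h, w = image_shape
    s = grid.patch_size
    vsum = np.zeros((h + 1, w + 1))
    count = np.zeros((h + 1, w + 1), dtype=np.int64)
    for (x0, y0), v in zip(grid.boxes, vals):
        x1, y1 = min(x0 + s, w), min(y0 + s, h)
        for arr, inc in ((vsum, v), (count, 1)):
            arr[y0, x0] += inc
            arr[y0, x1] -= inc
            arr[y1, x0] -= inc
            arr[y1, x1] += inc
    vsum = vsum.cumsum(0).cumsum(1)[:h, :w]
    count = count.cumsum(0).cumsum(1)[:h, :w]
    values = np.full((h, w), np.nan)
    covered = count > 0
    values[covered] = vsum[covered] / count[covered]
    return Heatmap(values=values, coverage=count)


def render_heatmap(heatmap: Heatmap, out_path=None, vmax: float | None = None) -> np.ndarray:
    """Render to an RGB raster: red positive, blue negative, grey no-data.

    The color scale is symmetric about 0 (vmax defaults to the largest
    absolute covered value).
    """
    vals = heatmap.values
    covered = ~heatmap.nodata
    if vmax is None:
        vmax = float(np.nanmax(np.abs(vals))) if covered.any() else 1.0
        vmax = vmax or 1.0
    cmap = colormaps["bwr"]  # low = blue, high = red
    norm = np.clip((vals + vmax) / (2.0 * vmax), 0.0, 1.0)
    rgb = np.empty((*vals.shape, 3), dtype=np.uint8)
    rgb[:] = NODATA_GREY
    colored = (cmap(norm[covered])[:, :3] * 255).round().astype(np.uint8)
    rgb[covered] = colored
    if out_path is not None:
        Image.fromarray(rgb, mode="RGB").save(out_path)
    return rgb


def top_activating_patches(
    features: np.ndarray,
    provenance,
    model: LinearModel,
    n_dims: int = 6,
    n_patches: int = 5,
) -> list[dict]:
    """Gallery of the patches that most activate the top-weight dimensions.

    ``features`` is the full N x D patch feature matrix; ``provenance`` maps
    each row to its source, e.g. (image index, box).  The ``n_dims``
    dimensions with the largest positive weight of the model's (first)
    decision function are ranked descending; for each, the ``n_patches``
    rows with the largest value in that dimension are listed descending,
    ties by row order.  Returns a flat list of gallery entries.
    """
    x = np.asarray(features, dtype=np.float64)
    provenance = list(provenance)
    if x.shape[0] != len(provenance):
        raise InputError("provenance must map every feature row")
    w = np.asarray(model.weights[0], dtype=np.float64)
    # weights live in selected-feature space; map back to original dims
    if model.selected_indices is not None:
        full = np.full(x.shape[1], -np.inf)
        full[model.selected_indices] = w
        w = full
    if n_dims > x.shape[1]:
        raise ParameterError(f"n_dims={n_dims} exceeds feature dimension {x.shape[1]}")
    dim_order = np.argsort(-w, kind="stable")[:n_dims]
    gallery = []
    for dim_rank, dim in enumerate(dim_order):
        row_order = np.argsort(-x[:, dim], kind="stable")[:n_patches]
        for rank, row in enumerate(row_order):
            gallery.append(
                {
                    "dim": int(dim),
                    "weight": float(w[dim]),
                    "dim_rank": dim_rank,
                    "rank": rank,
                    "row": int(row),
                    "source": provenance[row],
                    "value": float(x[row, dim]),
                }
            )
    return gallery
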