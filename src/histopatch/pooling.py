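"""P-norm pooling of patch features and mean-difference feature selection.

One slide yields hundreds of patch feature vectors; classification needs a
single image-level vector.  P-norm pooling (also called softmax pooling)
takes, component-wise, the generalized power mean

    f_P = ( (1/N) * sum_i v_i^P )^(1/P)

over the N patch vectors v_i.  P = 1 is the arithmetic mean; as P grows the
pool approaches the component-wise maximum, amplifying the few strongest
patch responses — the behaviour wanted when only a small part of a slide
carries the diagnostic signal.  The default P = 3 balances the two regimes.

For binary tasks, discriminative components are ranked by the absolute
difference of class means over image-level vectors,

    diff_k = | mean_{i in pos} v_{i,k} - mean_{i in neg} v_{i,k} |,

and the top k (default 100) are kept.  Multiclass tasks use the full vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from histopatch.errors import InputError, ParameterError

DEFAULT_K_SELECT = 100


@dataclass
class PoolingConfig:
    """Pooling exponent; P >= 1 keeps the power-mean bounds [mean, max]."""

    P: float = 3.0

    def __post_init__(self) -> None:
        if self.P < 1:
            raise ParameterError("pooling exponent P must be >= 1")


@dataclass
class SelectionResult:
    """Mean-difference ranking: diffs per dimension plus the chosen indices.

    ``selected`` is sorted by descending diff, ties broken by ascending
    index; ``n_pos``/``n_neg`` record the class sizes the means used.
    """

    diffs: np.ndarray
    selected: np.ndarray
    n_pos: int
    n_neg: int


def _validated(matrix) -> np.ndarray:
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] < 1:
        raise InputError(f"expected a nonempty N x D matrix, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise InputError("feature matrix contains non-finite entries")
    if (m < 0).any():
        raise InputError("P-norm pooling requires nonnegative features")
    return m


def pnorm_pool(matrix, cfg: PoolingConfig | None = None) -> np.ndarray:
    """Component-wise P-norm pool of an N x D nonnegative matrix.

    Computed in a max-factored form for numerical stability at large P;
    for P >= 1 every component lies between the column mean and the column
    maximum.
    """
    cfg = cfg or PoolingConfig()
    m = _validated(matrix)
    if cfg.P == 1.0:
        return m.mean(axis=0)
    col_max = m.max(axis=0)
    out = np.zeros(m.shape[1])
    nz = col_max > 0
    if nz.any():
        scaled = m[:, nz] / col_max[nz]
        out[nz] = col_max[nz] * (scaled**cfg.P).mean(axis=0) ** (1.0 / cfg.P)
    return out


def feature_diff(pos_features, neg_features) -> np.ndarray:
    """Absolute difference of class means, one value per feature dimension.

    Inputs are image-level (pooled) vectors, one row per image.
    """
    pos = np.asarray(pos_features, dtype=np.float64)
    neg = np.asarray(neg_features, dtype=np.float64)
    if pos.ndim != 2 or neg.ndim != 2 or pos.shape[0] < 1 or neg.shape[0] < 1:
        raise InputError("both classes need at least one image-level vector")
    if pos.shape[1] != neg.shape[1]:
        raise InputError("positive and negative features disagree on dimension")
    return np.abs(pos.mean(axis=0) - neg.mean(axis=0))


def select_top_k(diffs, k: int, n_pos: int = 0, n_neg: int = 0) -> SelectionResult:
    """Indices of the k largest diffs, descending, ties by ascending index."""
    d = np.asarray(diffs, dtype=np.float64).ravel()
    if not (1 <= k <= d.shape[0]):
        raise ParameterError(f"k must lie in [1, {d.shape[0]}], got {k}")
    # stable sort on -diff keeps ascending-index order within ties
    order = np.argsort(-d, kind="stable")
    return SelectionResult(diffs=d, selected=order[:k].copy(), n_pos=n_pos, n_neg=n_neg)
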