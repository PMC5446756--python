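"""Scoring of segmentations and classifications.

The per-image segmentation score compares the predicted positive pixel set
P with the ground truth G.  Two denominator conventions are provided:

* ``dice_sum`` (default): 2|P∩G| / (|P| + |G|) — the Dice coefficient,
  bounded by 1, consistent with scores reported as percentages.
* ``literal_union``: 2|P∩G| / |P∪G| — the formula exactly as printed in the
  source challenge rule, which reaches 2 at perfect overlap.

The discrepancy between the printed formula and the percentage scale of
reported results is surfaced here rather than silently resolved; both
conventions agree at 0 (disjoint sets) and both are symmetric.  When P and
G are both empty the score is defined as 1 (perfect agreement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from histopatch.errors import InputError


@dataclass
class ScoreReport:
    """Per-image scores and their arithmetic mean over K images."""

    per_image_scores: list[float]
    mean_score: float
    K: int


def overlap_score(pred, truth, convention: str = "dice_sum") -> float:
    """Similarity of two binary masks under the chosen denominator convention."""
    p = np.asarray(pred) > 0
    g = np.asarray(truth) > 0
    if p.shape != g.shape:
        raise InputError(f"mask shapes differ: {p.shape} vs {g.shape}")
    inter = np.logical_and(p, g).sum()
    np_, ng = p.sum(), g.sum()
    if np_ == 0 and ng == 0:
        return 1.0
    if convention == "dice_sum":
        return float(2.0 * inter / (np_ + ng))
    if convention == "literal_union":
        return float(2.0 * inter / np.logical_or(p, g).sum())
    raise InputError(f"unknown convention {convention!r}")


def mean_score(scores) -> float:
    """Arithmetic mean of per-image scores."""
    s = list(scores)
    if not s:
        raise InputError("cannot average an empty score list")
    return float(np.mean(s))


def score_masks(preds, truths, convention: str = "dice_sum") -> ScoreReport:
    """Score a matched list of predicted/true masks and average."""
    preds, truths = list(preds), list(truths)
    if len(preds) != len(truths):
        raise InputError("prediction and truth lists differ in length")
    per = [overlap_score(p, g, convention) for p, g in zip(preds, truths)]
    return ScoreReport(per_image_scores=per, mean_score=mean_score(per), K=len(per))


def classification_accuracy(predicted, true) -> float:
    """Fraction of matching labels."""
    pred = list(predicted)
    truth = list(true)
    if len(pred) != len(truth):
        raise InputError("label lists differ in length")
    if not pred:
        raise InputError("empty label lists")
    return float(np.mean([p == t for p, t in zip(pred, truth)]))
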