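"""Patch labeling, majority voting, smoothing, and their composition."""

import numpy as np
import pytest

import histopatch as hp
from histopatch.classify import LinearModel
from histopatch.errors import ConfigurationError
from histopatch.segment import SegConfig
from histopatch.tiling import PatchGrid


def _grid(boxes, size):
    return PatchGrid(boxes=boxes, patch_size=size)


class TestLabelPatchesFromMask:
    def test_fully_inside_positive_region(self):
        mask = np.ones((20, 20), dtype=np.uint8)
        labels = hp.label_patches_from_mask(_grid([(0, 0)], 10), mask, SegConfig(patch_size=10))
        assert labels.tolist() == [1]

    def test_ratio_exactly_at_threshold_is_negative(self):
        """Overlap 0.6 exactly -> negative: the rule is strictly 'larger than'."""
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[:6, :] = 1  # box (0,0) size 10 -> ratio exactly 0.6
        labels = hp.label_patches_from_mask(_grid([(0, 0)], 10), mask, SegConfig(patch_size=10))
        assert labels.tolist() == [0]
        mask[6, 0] = 1  # one more pixel -> ratio 0.61
        labels = hp.label_patches_from_mask(_grid([(0, 0)], 10), mask, SegConfig(patch_size=10))
        assert labels.tolist() == [1]

    def test_half_covered_box_is_negative(self):
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[:, :8] = 1
        labels = hp.label_patches_from_mask(_grid([(0, 0)], 16), mask, SegConfig(patch_size=16))
        assert labels.tolist() == [0]

    def test_matches_direct_counting_on_random_masks(self):
        rng = np.random.default_rng(0)
        cfg = SegConfig(patch_size=8)
        for _ in range(20):
            mask = (rng.random((40, 40)) < 0.4).astype(np.uint8)
            grid = hp.generate_grid(
                hp.SlideImage(np.zeros((40, 40, 3), dtype=np.uint8)),
                hp.TilingConfig(patch_size=8, stride=4),
            )
            labels = hp.label_patches_from_mask(grid, mask, cfg)
            for (x0, y0), lab in zip(grid.boxes, labels):
                ratio = mask[y0 : y0 + 8, x0 : x0 + 8].sum() / 64.0
                assert lab == (1 if ratio > 0.6 else 0)


def brute_force_vote(boxes, size, labels, shape):
    """Per-pixel counting oracle."""
    h, w = shape
    pos = np.zeros((h, w), dtype=int)
    neg = np.zeros((h, w), dtype=int)
    for (x0, y0), lab in zip(boxes, labels):
        target = pos if lab > 0 else neg
        target[y0 : y0 + size, x0 : x0 + size] += 1
    return (pos > neg).astype(np.uint8)


class TestVotePixels:
    def test_majority_positive(self):
        # three stacked boxes, labels +,+,- -> covered pixels positive
        boxes = [(0, 0), (0, 0), (0, 0)]
        out = hp.vote_pixels(_grid(boxes, 4), [1, 1, 0], (6, 6))
        assert out[:4, :4].all()
        assert out[4:, :].sum() == 0 and out[:, 4:].sum() == 0

    def test_tie_is_negative(self):
        out = hp.vote_pixels(_grid([(0, 0), (0, 0)], 4), [1, 0], (4, 4))
        assert out.sum() == 0

    def test_uncovered_pixels_negative(self):
        out = hp.vote_pixels(_grid([(0, 0)], 2), [1], (8, 8))
        assert out[:2, :2].all() and out.sum() == 4

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            h, w = rng.integers(20, 65), rng.integers(20, 65)
            img = hp.SlideImage(np.zeros((h, w, 3), dtype=np.uint8))
            grid = hp.generate_grid(img, hp.TilingConfig(patch_size=16, stride=4))
            if not grid.boxes:
                continue
            labels = rng.integers(0, 2, size=len(grid.boxes))
            fast = hp.vote_pixels(grid, labels, (h, w))
            assert np.array_equal(fast, brute_force_vote(grid.boxes, 16, labels, (h, w)))


class TestSmoothRegions:
    def test_small_positive_component_removed(self):
        mask = np.zeros((100, 100), dtype=np.uint8)
        mask[10:30, 10:30] = 1  # 400 px < 500 threshold
        assert hp.smooth_regions(mask, SegConfig()).sum() == 0

    def test_component_at_threshold_kept(self):
        mask = np.zeros((100, 100), dtype=np.uint8)
        mask[10:30, 10:35] = 1  # exactly 500 px = 5% -> kept ("less than" is strict)
        out = hp.smooth_regions(mask, SegConfig())
        assert out.sum() == 500

    def test_small_hole_filled(self):
        mask = np.ones((100, 100), dtype=np.uint8)
        mask[40:60, 40:60] = 0  # 400-px hole -> filled
        assert hp.smooth_regions(mask, SegConfig()).all()

    def test_all_zero_unchanged(self):
        mask = np.zeros((50, 50), dtype=np.uint8)
        assert hp.smooth_regions(mask, SegConfig()).sum() == 0

    def test_idempotent_on_random_masks(self):
        rng = np.random.default_rng(2)
        cfg = SegConfig()
        for _ in range(30):
            mask = (rng.random((64, 64)) < rng.uniform(0.2, 0.8)).astype(np.uint8)
            once = hp.smooth_regions(mask, cfg)
            twice = hp.smooth_regions(once, cfg)
            assert np.array_equal(once, twice)

    def test_never_leaves_small_positive_component(self):
        from skimage.measure import label as cc_label

        rng = np.random.default_rng(3)
        cfg = SegConfig()
        for _ in range(20):
            mask = (rng.random((60, 60)) < 0.5).astype(np.uint8)
            out = hp.smooth_regions(mask, cfg)
            lab = cc_label(out, connectivity=2)
            for region in range(1, lab.max() + 1):
                assert (lab == region).sum() >= 0.05 * 60 * 60


@pytest.fixture(scope="module")
def tiny_seg_setup():
    """Small slides + trained patch model for fast composition tests."""
    import dataclasses

    params = hp.SynthParams(seed=0, image_height=320, image_width=320)
    train = hp.make_segmentation_dataset(4, params)
    ext = hp.reference_extractor()
    cfg = SegConfig(patch_size=64, stride=16, target_size=64, min_region_fraction=0.02)
    model = hp.train_patch_classifier(train, ext, cfg, hp.TrainConfig(seed=0, k_select=None))
    test_params = dataclasses.replace(params, seed=99)
    test = hp.make_segmentation_dataset(2, test_params)
    return model, ext, cfg, test


def test_predict_patch_labels_structure(tiny_seg_setup):
    model, ext, cfg, test = tiny_seg_setup
    labels, decisions, grid = hp.predict_patch_labels(model, test[0]["image"], ext, cfg)
    assert len(labels) == len(grid.boxes) == len(decisions)
    assert set(np.unique(labels)).issubset({0, 1})


def test_predicted_labels_track_tumor_interior(tiny_seg_setup):
    """Boxes fully inside the tumor region are overwhelmingly predicted positive."""
    model, ext, cfg, test = tiny_seg_setup
    rec = test[0]
    labels, _, grid = hp.predict_patch_labels(model, rec["image"], ext, cfg)
    inside = [
        i
        for i, (x0, y0) in enumerate(grid.boxes)
        if rec["mask"][y0 : y0 + cfg.patch_size, x0 : x0 + cfg.patch_size].all()
    ]
    assert inside, "test slide should contain fully-interior boxes"
    assert np.mean([labels[i] for i in inside]) > 0.9


def test_segment_image_composition_scores_well(tiny_seg_setup):
    model, ext, cfg, test = tiny_seg_setup
    for rec in test:
        pred = hp.segment_image(model, rec["image"], ext, cfg)
        assert pred.shape == rec["image"].shape
        assert hp.overlap_score(pred, rec["mask"]) > 0.7


def test_all_negative_model_gives_empty_mask(tiny_seg_setup):
    _, ext, cfg, test = tiny_seg_setup
    always_neg = LinearModel(
        classes=["0", "1"],
        weights=np.zeros((1, ext.output_dim)),
        biases=np.array([-1.0]),
        extractor_name=ext.name,
        patch_size=cfg.patch_size,
    )
    pred = hp.segment_image(always_neg, test[0]["image"], ext, cfg)
    assert pred.sum() == 0


def test_predict_rejects_mismatched_patch_size(tiny_seg_setup):
    model, ext, cfg, test = tiny_seg_setup
    import dataclasses

    wrong = dataclasses.replace(cfg, patch_size=112)
    with pytest.raises(ConfigurationError):
        hp.predict_patch_labels(model, test[0]["image"], ext, wrong)


def test_decision_zero_is_negative():
    model = LinearModel(classes=["0", "1"], weights=np.zeros((1, 4)), biases=np.array([0.0]))
    # decision exactly 0 -> negative by tie policy
    assert model.predict(np.ones((1, 4))) == ["0"]
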