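"""Overlap scoring identities and visualization oracles."""

import numpy as np
import pytest

import histopatch as hp
from histopatch.classify import LinearModel
from histopatch.errors import InputError, ParameterError
from histopatch.tiling import PatchGrid


def _mask(shape, fill=0):
    return np.full(shape, fill, dtype=np.uint8)


class TestOverlapScore:
    def test_identical_nonempty(self):
        m = _mask((10, 10), 1)
        assert hp.overlap_score(m, m, "dice_sum") == 1.0
        assert hp.overlap_score(m, m, "literal_union") == 2.0

    def test_disjoint_nonempty(self):
        a, b = _mask((10, 10)), _mask((10, 10))
        a[:2], b[8:] = 1, 1
        assert hp.overlap_score(a, b, "dice_sum") == 0.0
        assert hp.overlap_score(a, b, "literal_union") == 0.0

    def test_half_overlap_values(self):
        # |P| = |G| = 100, |P∩G| = 50
        a, b = _mask((20, 20)), _mask((20, 20))
        a[:5, :20] = 1  # rows 0-4
        b[2:7, :20] = 1  # rows 2-6, overlap rows 2-4 = 60... use columns instead
        a[:], b[:] = 0, 0
        a[0:5, 0:20] = 1  # 100 px
        b[0:5, 10:20] = 1
        b[5:10, 0:10] = 1  # 100 px, intersection = 50
        assert hp.overlap_score(a, b, "dice_sum") == 0.5
        assert np.isclose(hp.overlap_score(a, b, "literal_union"), 100.0 / 150.0)

    def test_both_empty_scores_one(self):
        assert hp.overlap_score(_mask((5, 5)), _mask((5, 5))) == 1.0

    def test_symmetry_and_ranges_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            a = (rng.random((16, 16)) < 0.5).astype(np.uint8)
            b = (rng.random((16, 16)) < 0.5).astype(np.uint8)
            for conv, hi in (("dice_sum", 1.0), ("literal_union", 2.0)):
                s_ab = hp.overlap_score(a, b, conv)
                assert s_ab == hp.overlap_score(b, a, conv)
                assert 0.0 <= s_ab <= hi

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InputError):
            hp.overlap_score(_mask((4, 4)), _mask((5, 5)))


def test_mean_score_examples():
    assert hp.mean_score([1.0, 0.0]) == 0.5
    assert hp.mean_score([0.42]) == 0.42
    assert np.isclose(hp.mean_score([0.5, 0.7, 0.9]), 0.7)
    with pytest.raises(InputError):
        hp.mean_score([])


def test_classification_accuracy_counting():
    assert hp.classification_accuracy(["a", "b"], ["a", "b"]) == 1.0
    assert hp.classification_accuracy(["a", "a"], ["b", "b"]) == 0.0
    assert hp.classification_accuracy(["a", "b", "a", "b"], ["a", "b", "a", "a"]) == 0.75


def brute_force_heatmap(boxes, size, values, shape):
    h, w = shape
    sums = np.zeros((h, w))
    counts = np.zeros((h, w), dtype=int)
    for (x0, y0), v in zip(boxes, values):
        sums[y0 : y0 + size, x0 : x0 + size] += v
        counts[y0 : y0 + size, x0 : x0 + size] += 1
    out = np.full((h, w), np.nan)
    out[counts > 0] = sums[counts > 0] / counts[counts > 0]
    return out, counts


class TestBuildHeatmap:
    def test_single_full_box_constant(self):
        grid = PatchGrid(boxes=[(0, 0)], patch_size=8)
        hm = hp.build_heatmap(grid, [2.5], (8, 8))
        assert (hm.values == 2.5).all()
        assert (hm.coverage == 1).all()

    def test_half_overlapping_boxes_average(self):
        grid = PatchGrid(boxes=[(0, 0), (4, 0)], patch_size=8)
        hm = hp.build_heatmap(grid, [0.0, 1.0], (8, 12))
        assert (hm.values[:, 4:8] == 0.5).all()
        assert (hm.values[:, :4] == 0.0).all()
        assert (hm.values[:, 8:] == 1.0).all()

    def test_uncovered_margin_flagged_nodata(self):
        grid = PatchGrid(boxes=[(0, 0)], patch_size=4)
        hm = hp.build_heatmap(grid, [1.0], (8, 8))
        assert hm.nodata[4:, :].all() and hm.nodata[:, 4:].all()
        assert np.isnan(hm.values[5, 5])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            h, w = rng.integers(20, 65), rng.integers(20, 65)
            img = hp.SlideImage(np.zeros((h, w, 3), dtype=np.uint8))
            grid = hp.generate_grid(img, hp.TilingConfig(patch_size=16, stride=4))
            if not grid.boxes:
                continue
            values = rng.normal(size=len(grid.boxes))
            hm = hp.build_heatmap(grid, values, (h, w))
            ref_vals, ref_counts = brute_force_heatmap(grid.boxes, 16, values, (h, w))
            assert np.array_equal(hm.coverage, ref_counts)
            assert np.allclose(hm.values, ref_vals, equal_nan=True)


def test_render_heatmap_red_positive_blue_negative_grey_nodata(tmp_path):
    grid = PatchGrid(boxes=[(0, 0), (8, 0)], patch_size=8)
    hm = hp.build_heatmap(grid, [5.0, -5.0], (12, 16))
    rgb = hp.render_heatmap(hm, tmp_path / "h.png")
    assert rgb[2, 2, 0] > rgb[2, 2, 2]  # positive zone: red dominates
    assert rgb[2, 12, 2] > rgb[2, 12, 0]  # negative zone: blue dominates
    assert tuple(rgb[10, 2]) == (128, 128, 128)  # uncovered: grey
    assert (tmp_path / "h.png").exists()


class TestTopActivatingPatches:
    def _model(self, weights):
        w = np.asarray(weights, dtype=np.float64)
        return LinearModel(classes=["neg", "pos"], weights=w[None, :], biases=np.zeros(1))

    def test_unique_max_weight_dim_listed_first(self):
        feats = np.eye(4)
        prov = [("img", (0, 0))] * 4
        gallery = hp.top_activating_patches(feats, prov, self._model([0.1, 0.9, 0.2, 0.3]), 2, 1)
        assert gallery[0]["dim"] == 1
        assert gallery[1]["dim"] == 3

    def test_row_maximizing_dim_ranks_first(self):
        rng = np.random.default_rng(2)
        feats = rng.random((10, 5))
        feats[7, 2] = 10.0
        prov = [("img", (i, 0)) for i in range(10)]
        gallery = hp.top_activating_patches(feats, prov, self._model([0, 0, 1, 0, 0]), 1, 3)
        assert gallery[0]["dim"] == 2 and gallery[0]["row"] == 7

    def test_gallery_size_six_by_five(self):
        rng = np.random.default_rng(3)
        feats = rng.random((40, 8))
        prov = [("img", (i, 0)) for i in range(40)]
        gallery = hp.top_activating_patches(feats, prov, self._model(rng.random(8)), 6, 5)
        assert len(gallery) == 30
        assert len({(e["dim"], e["rank"]) for e in gallery}) == 30

    def test_selection_maps_back_to_original_dims(self):
        feats = np.eye(6)
        prov = [("img", (i, 0)) for i in range(6)]
        model = LinearModel(
            classes=["neg", "pos"],
            weights=np.array([[0.5, 2.0]]),
            biases=np.zeros(1),
            selected_indices=np.array([4, 1]),
        )
        gallery = hp.top_activating_patches(feats, prov, model, 1, 1)
        assert gallery[0]["dim"] == 1  # weight 2.0 lives on original dim 1

    def test_n_dims_beyond_dimension_rejected(self):
        with pytest.raises(ParameterError):
            hp.top_activating_patches(np.ones((2, 3)), [1, 2], self._model([1, 2, 3]), 4, 1)

    def test_ties_break_by_row_order(self):
        feats = np.ones((5, 2))
        prov = list(range(5))
        gallery = hp.top_activating_patches(feats, prov, self._model([1.0, 0.5]), 1, 3)
        assert [e["row"] for e in gallery] == [0, 1, 2]


def test_score_masks_report():
    a = _mask((10, 10), 1)
    b = _mask((10, 10), 0)
    rep = hp.score_masks([a, b], [a, a])
    assert rep.K == 2
    assert rep.per_image_scores == [1.0, 0.0]
    assert rep.mean_score == 0.5
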