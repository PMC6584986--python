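"""ZNCC maps, grouped-template scoring, NMS, and the threshold sweep."""

import numpy as np
import pytest

from standcount.io_geo import PointSet
from standcount.matching import (
    Detection,
    ScoreMap,
    combined_score_map,
    detect_seedlings,
    match_detections,
    threshold_sweep,
    zncc_map,
)
from standcount.templates import GroupedTemplate, PatchSet, build_grouped_template, normalize_patch
from standcount.vegetation import PlantLayer, filter_components

from _oracles import brute_force_zncc, greedy_nms_reference


def _score_map_from(scores, k=1):
    valid = np.isfinite(scores)
    return ScoreMap(
        scores=np.where(valid, scores, -np.inf),
        argmax_group=np.where(valid, 1, 0).astype(np.int32),
        valid=valid,
        k=k,
    )


class TestZncc:
    def test_self_correlation_is_one(self, rng):
        template = rng.random((8, 8))
        layer = np.zeros((30, 30))
        layer[10:18, 12:20] = template
        sm = zncc_map(layer, template)
        assert sm[14, 16] == pytest.approx(1.0, abs=1e-9)

    def test_affine_invariance(self, rng):
        template = rng.random((8, 8))
        layer = np.zeros((30, 30))
        layer[10:18, 12:20] = 2.0 * template + 7.0
        assert zncc_map(layer, template)[14, 16] == pytest.approx(1.0, abs=1e-9)

    def test_flat_window_scores_zero(self):
        layer = np.full((20, 20), 3.0)
        template = np.random.default_rng(0).random((6, 6))
        sm = zncc_map(layer, template)
        assert (sm[3:17, 3:17] == 0.0).all()

    def test_matches_brute_force(self, rng):
        layer = rng.random((64, 64)) * 200
        template = rng.random((8, 8))
        fast = zncc_map(layer, template)
        slow = brute_force_zncc(layer, template)
        valid = ~np.isnan(slow)
        np.testing.assert_allclose(fast[valid], slow[valid], atol=1e-6)
        assert np.isnan(fast[~valid]).all()

    def test_template_larger_than_layer_rejected(self, rng):
        with pytest.raises(ValueError):
            zncc_map(rng.random((5, 5)), rng.random((8, 8)))


def _grouped(templates_arr):
    k = len(templates_arr)
    return GroupedTemplate(
        templates=np.stack([normalize_patch(t) for t in templates_arr]),
        assignment=np.arange(k),
        quality_per_group=np.ones(k),
        quality_R=1.0,
    )


class TestCombinedScoreMap:
    def test_k1_reduces_to_zncc_on_valid_region(self, rng):
        values = rng.random((40, 40)) * 150
        mask = filter_components(values > 40, min_size=1)
        layer = PlantLayer(values=np.where(mask.mask, values, 0.0), channel="green", mask=mask)
        template = rng.random((8, 8))
        sm = combined_score_map(layer, _grouped([template]))
        ref = zncc_map(layer.values, template)
        np.testing.assert_allclose(sm.scores[sm.valid], ref[sm.valid], atol=1e-9)
        assert (sm.argmax_group[sm.valid] == 1).all()

    def test_planted_template_wins_its_location(self, rng):
        t1, t2, t3 = (rng.random((8, 8)) for _ in range(3))
        values = np.zeros((50, 50))
        values[21:29, 21:29] = t2 * 100 + 20
        mask = filter_components(values > 0, min_size=1)
        layer = PlantLayer(values=values, channel="green", mask=mask)
        sm = combined_score_map(layer, _grouped([t1, t2, t3]))
        assert sm.argmax_group[25, 25] == 2
        assert sm.scores[25, 25] == pytest.approx(1.0, abs=1e-9)

    def test_all_background_has_no_valid_pixels(self):
        mask = filter_components(np.zeros((30, 30), bool), min_size=1)
        layer = PlantLayer(values=np.zeros((30, 30)), channel="green", mask=mask)
        sm = combined_score_map(layer, _grouped([np.eye(6)]))
        assert not sm.valid.any()

    def test_masked_equals_full_frame_brute_force(self, rng):
        """The sparse (bounding-box) evaluation path equals direct ZNCC."""
        values = (rng.random((64, 64)) > 0.92) * rng.random((64, 64)) * 200
        mask = filter_components(values > 0, min_size=1)
        layer = PlantLayer(values=values, channel="green", mask=mask)
        template = rng.random((8, 8))
        sm = combined_score_map(layer, _grouped([template]))
        slow = brute_force_zncc(values, template)
        np.testing.assert_allclose(sm.scores[sm.valid], slow[sm.valid], atol=1e-6)


class TestDetect:
    def test_single_peak(self):
        scores = np.full((30, 30), 0.1)
        scores[12, 14] = 0.8
        dets = detect_seedlings(_score_map_from(scores), threshold=0.5)
        assert len(dets) == 1
        assert (dets[0].col, dets[0].row, dets[0].score) == (14, 12, pytest.approx(0.8))

    def test_close_peaks_suppressed(self):
        scores = np.zeros((30, 30))
        scores[10, 10] = 0.9
        scores[10, 15] = 0.7  # distance 5 < radius 10
        dets = detect_seedlings(_score_map_from(scores), threshold=0.5, nms_radius=10)
        assert len(dets) == 1 and dets[0].score == pytest.approx(0.9)

    def test_matches_quadratic_reference(self, rng):
        scores = np.full((120, 120), -np.inf)
        cand = []
        for _ in range(200):
            r, c = rng.integers(0, 120, 2)
            v = float(rng.uniform(0.3, 1.0))
            scores[r, c] = max(scores[r, c], v)
        rows, cols = np.nonzero(np.isfinite(scores))
        cand = [(int(c), int(r), float(scores[r, c])) for r, c in zip(rows, cols)
                if scores[r, c] > 0.5]
        dets = detect_seedlings(_score_map_from(scores), threshold=0.5, nms_radius=9)
        ref = greedy_nms_reference(cand, 9)
        assert [(d.col, d.row, pytest.approx(d.score)) for d in dets] == ref

    def test_tie_break_lower_row_then_col(self):
        scores = np.full((40, 40), -np.inf)
        scores[5, 30] = 0.7
        scores[5, 10] = 0.7
        scores[20, 10] = 0.7
        dets = detect_seedlings(_score_map_from(scores), threshold=0.5, nms_radius=50)
        assert [(d.row, d.col) for d in dets] == [(5, 10)]

    def test_threshold_one_yields_nothing(self):
        scores = np.full((10, 10), 0.99)
        assert detect_seedlings(_score_map_from(scores), threshold=1.0) == []
        with pytest.raises(ValueError):
            detect_seedlings(_score_map_from(scores), threshold=1.5)


class TestSweep:
    def test_count_monotone_in_threshold(self, rng):
        scores = rng.uniform(-1, 1, (80, 80))
        sm = _score_map_from(scores)
        table = threshold_sweep(sm, [0.2, 0.4, 0.6, 0.8])
        counts = [row["count"] for row in table]
        assert counts == sorted(counts, reverse=True)

    def test_unsorted_thresholds_rejected(self, rng):
        sm = _score_map_from(rng.uniform(-1, 1, (20, 20)))
        with pytest.raises(ValueError):
            threshold_sweep(sm, [0.6, 0.4])

    def test_precision_recall_against_truth(self):
        scores = np.full((60, 60), -np.inf)
        truth = np.array([[10, 10], [40, 40], [20, 50]], float)
        for col, row in truth[:2]:  # two found, one missed
            scores[int(row), int(col)] = 0.9
        scores[50, 55] = 0.9  # one spurious
        sm = _score_map_from(scores)
        row = threshold_sweep(sm, [0.5], truth=truth, tol=3.0)[0]
        assert row["count"] == 3
        assert row["precision"] == pytest.approx(2 / 3)
        assert row["recall"] == pytest.approx(2 / 3)


class TestMatchDetections:
    def test_greedy_one_to_one(self):
        dets = [
            Detection(col=10, row=10, score=0.9, subgroup=1),
            Detection(col=12, row=10, score=0.8, subgroup=1),
        ]
        truth = np.array([[11.0, 10.0]])
        tp, fp, fn = match_detections(dets, truth, tol=5)
        assert (tp, fp, fn) == (1, 1, 0)

    def test_empty_truth(self):
        dets = [Detection(col=1, row=1, score=0.9, subgroup=1)]
        assert match_detections(dets, np.empty((0, 2)), tol=5) == (0, 1, 0)
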