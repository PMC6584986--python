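"""Patch extraction, subgroup clustering, and template quality."""

import itertools

import numpy as np
import pytest

from standcount.io_geo import GeoImage, PointSet
from standcount.synthetic_field import render_seedling
from standcount.templates import (
    GroupedTemplate,
    PatchSet,
    build_grouped_template,
    compare_channels,
    extract_patches,
    load_template,
    normalize_patch,
    save_template,
    template_quality,
)
from standcount.vegetation import filter_components


def _rosette_patches(n, rng, size=20):
    """n patches of rendered rosettes on zero background, centre-cropped."""
    out = []
    for _ in range(n):
        rgb, alpha = render_seedling(int(rng.integers(2, 5)), 8.0,
                                     float(rng.uniform(0, 360)), rng)
        layer = np.where(alpha, rgb[:, :, 1], 0.0)
        c = layer.shape[0] // 2
        h = size // 2
        out.append(layer[c - h : c + h, c - h : c + h])
    return PatchSet(np.stack(out), PointSet(np.zeros((n, 2))))


class TestExtractPatches:
    def test_single_center_patch_size(self, rng):
        layer = rng.random((100, 100))
        ps = extract_patches(layer, PointSet(np.array([[50.0, 50.0]])), size=20)
        assert ps.patches.shape == (1, 20, 20)

    def test_border_centers_skipped_and_error_when_none_left(self, rng):
        layer = rng.random((100, 100))
        with pytest.raises(ValueError, match="retainable"):
            extract_patches(layer, PointSet(np.array([[0.0, 0.0]])), size=20)
        ps = extract_patches(
            layer, PointSet(np.array([[0.0, 0.0], [50.0, 50.0]])), size=20
        )
        assert len(ps) == 1 and ps.n_skipped == 1

    def test_matches_direct_slicing(self, rng):
        layer = rng.random((80, 90))
        pts = np.column_stack([rng.integers(15, 75, 10), rng.integers(15, 65, 10)]).astype(float)
        ps = extract_patches(layer, PointSet(pts), size=20)
        for patch, (col, row) in zip(ps.patches, pts):
            r0, c0 = int(row) - 10, int(col) - 10
            np.testing.assert_array_equal(patch, layer[r0 : r0 + 20, c0 : c0 + 20])


def _two_partition_objective(flat, assignment):
    """Within-cluster sum of squared distances to the centroid."""
    total = 0.0
    for g in (0, 1):
        members = flat[assignment == g]
        if len(members):
            total += ((members - members.mean(axis=0)) ** 2).sum()
    return total


class TestBuildGroupedTemplate:
    def test_identical_patches_k1(self):
        patch = np.arange(16.0).reshape(4, 4)
        ps = PatchSet(np.stack([patch] * 5), PointSet(np.zeros((5, 2))))
        gt = build_grouped_template(ps, k=1, seed=0)
        np.testing.assert_allclose(gt.templates[0], normalize_patch(patch), atol=1e-12)
        assert gt.quality_R == pytest.approx(1.0)

    def test_two_families_separated_optimally(self, rng):
        # "+" and "x" shaped patches; exhaustive search over 2-partitions
        plus = np.zeros((9, 9))
        plus[4, :] = plus[:, 4] = 1.0
        cross = np.eye(9) + np.eye(9)[::-1]
        patches = []
        for base in (plus, cross):
            for _ in range(5):
                patches.append(base + 0.05 * rng.standard_normal((9, 9)))
        ps = PatchSet(np.stack(patches), PointSet(np.zeros((10, 2))))
        gt = build_grouped_template(ps, k=2, seed=0)
        # families end up in different subgroups
        first, second = gt.assignment[:5], gt.assignment[5:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]
        # and the clustering attains the exhaustive-minimum objective
        flat = np.stack([normalize_patch(p).ravel() for p in patches])
        best = min(
            _two_partition_objective(flat, np.array(a))
            for a in itertools.product([0, 1], repeat=10)
            if len(set(a)) == 2
        )
        assert _two_partition_objective(flat, gt.assignment) == pytest.approx(best)

    def test_k10_on_rosette_patches_all_nonempty(self, rng):
        ps = _rosette_patches(1000, rng)
        gt = build_grouped_template(ps, k=10, seed=0)
        assert gt.k == 10
        assert len(np.unique(gt.assignment)) == 10

    def test_deterministic_under_seed(self, rng):
        ps = _rosette_patches(60, rng)
        a = build_grouped_template(ps, k=5, seed=11)
        b = build_grouped_template(ps, k=5, seed=11)
        np.testing.assert_array_equal(a.assignment, b.assignment)
        np.testing.assert_array_equal(a.templates, b.templates)

    def test_templates_zero_mean_unit_norm(self, rng):
        ps = _rosette_patches(60, rng)
        gt = build_grouped_template(ps, k=5, seed=0)
        for t in gt.templates:
            assert abs(t.mean()) < 1e-9
            assert np.linalg.norm(t) == pytest.approx(1.0, abs=1e-9)

    def test_k_bounds(self, rng):
        ps = _rosette_patches(5, rng)
        with pytest.raises(ValueError):
            build_grouped_template(ps, k=6)
        with pytest.raises(ValueError):
            build_grouped_template(ps, k=0)


class TestTemplateQuality:
    def test_identical_gives_one(self):
        patch = np.random.default_rng(0).random((8, 8))
        ps = PatchSet(np.stack([patch] * 4), PointSet(np.zeros((4, 2))))
        gt = build_grouped_template(ps, k=1, seed=0)
        R, per_group = template_quality(gt, ps)
        assert R == pytest.approx(1.0)
        assert per_group[0] == pytest.approx(1.0)

    def test_pure_noise_scores_near_zero(self):
        # Monte-Carlo: noise windows against a fixed template decorrelate
        rng = np.random.default_rng(99)
        template = normalize_patch(rng.random((20, 20)))
        gt = GroupedTemplate(
            templates=template[None],
            assignment=np.zeros(1, int),
            quality_per_group=np.ones(1),
            quality_R=1.0,
        )
        noise = PatchSet(rng.standard_normal((100, 20, 20)), PointSet(np.zeros((100, 2))))
        R, _ = template_quality(gt, noise)
        assert abs(R) < 0.1

    def test_affine_transformed_patches_score_one(self, rng):
        patch = rng.random((10, 10))
        ps = PatchSet(
            np.stack([2.0 * patch + 7.0, 0.5 * patch - 1.0, patch]),
            PointSet(np.zeros((3, 2))),
        )
        gt = build_grouped_template(ps, k=1, seed=0)
        R, _ = template_quality(gt, ps)
        assert R == pytest.approx(1.0)

    def test_quality_in_valid_range_and_nondecreasing_in_k(self, rng):
        ps = _rosette_patches(300, rng)
        scores = []
        for k in (1, 5, 10):
            gt = build_grouped_template(ps, k=k, seed=0)
            R, _ = template_quality(gt, ps)
            assert -1.0 <= R <= 1.0
            scores.append(R)
        assert scores == sorted(scores)


class TestChannelsAndArchive:
    def test_grayscale_image_symmetric_across_channels(self, rng):
        gray = rng.integers(20, 230, (120, 120)).astype(np.uint8)
        img = GeoImage(pixels=np.stack([gray] * 3, axis=2), gsd_cm=0.19)
        mask = filter_components(gray > 100, min_size=1)
        centers = PointSet(
            np.column_stack([rng.integers(20, 100, 30), rng.integers(20, 100, 30)]).astype(float)
        )
        table = compare_channels(img, mask, centers, k=3, seed=0)
        for kind in ("masked", "raw"):
            vals = list(table[kind].values())
            assert vals[0] == pytest.approx(vals[1]) == pytest.approx(vals[2])

    def test_archive_round_trip_bit_exact(self, rng, tmp_path):
        ps = _rosette_patches(40, rng)
        gt = build_grouped_template(ps, k=4, seed=2)
        path = save_template(gt, tmp_path / "template.json")
        back = load_template(path)
        np.testing.assert_array_equal(back.templates, gt.templates)
        np.testing.assert_array_equal(back.assignment, gt.assignment)
        assert back.quality_R == gt.quality_R
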