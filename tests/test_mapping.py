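"""Feature embedding, minimum-area rectangle, discretization, pixel maps."""

import math

import numpy as np
import pytest

from mrepinsight import (PixelMap, RepresentationSpec, TabularDataset,
                         compute_pixel_map, discretize, embed_features,
                         min_area_rectangle, pixel_distance)
from mrepinsight.mapping import _rotate


def _points_ds(points):
    """Dataset whose features embed at the given 2-D points under PCA-like maps."""
    return TabularDataset(values=np.asarray(points, dtype=float))


def sweep_oracle(points, step_deg=0.05):
    """Brute-force minimum bounding-box area over a dense rotation sweep."""
    points = np.asarray(points, dtype=float)
    best = math.inf
    for deg in np.arange(0.0, 90.0, step_deg):
        rp = _rotate(points, deg)
        ext = rp.max(axis=0) - rp.min(axis=0)
        best = min(best, float(ext[0] * ext[1]))
    return best


def rect_area(corners):
    e1 = np.linalg.norm(corners[1] - corners[0])
    e2 = np.linalg.norm(corners[3] - corners[0])
    return e1 * e2


class TestRepresentationSpec:
    def test_metric_only_for_tsne(self):
        with pytest.raises(ValueError, match="tsne"):
            RepresentationSpec(technique="pca", metric="euclidean")

    def test_assignment_filter_rejected(self):
        with pytest.raises(NotImplementedError, match="assignment"):
            RepresentationSpec(technique="tsne", filter="assignment")

    @pytest.mark.parametrize("kwargs", [
        {"technique": "isomap"}, {"filter": "sharpen"},
        {"technique": "tsne", "metric": "manhattan"},
    ])
    def test_invalid_fields_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RepresentationSpec(**kwargs)

    def test_json_round_trip(self, tmp_path):
        spec = RepresentationSpec(technique="tsne", metric="hamming",
                                  filter="blur", params={"sigma": 2.0}, seed=7)
        assert RepresentationSpec.from_dict(spec.to_dict()) == spec


class TestEmbedFeatures:
    def test_pca_on_collinear_features(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=10)
        points = np.outer(np.linspace(-2, 2, 6), t)  # 6 features on a line
        emb = embed_features(_points_ds(points), RepresentationSpec(technique="pca"))
        assert emb[:, 1].var() < 1e-10 * max(emb[:, 0].var(), 1e-30)

    def test_duplicated_features_embed_identically(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(5, 30))
        points = np.vstack([base, base[2]])  # feature 5 duplicates feature 2
        for technique in ("pca", "kpca"):
            emb = embed_features(_points_ds(points), RepresentationSpec(technique=technique))
            np.testing.assert_allclose(emb[5], emb[2], atol=1e-8)

    def test_pca_equals_dense_eigensolver_oracle(self):
        rng = np.random.default_rng(2)
        points = rng.normal(size=(15, 40))
        emb = embed_features(_points_ds(points), RepresentationSpec(technique="pca"))
        centered = points - points.mean(axis=0)
        evals, evecs = np.linalg.eigh(centered.T @ centered)
        proj = centered @ evecs[:, ::-1][:, :2]
        for k in range(2):  # sign of each eigenvector is arbitrary
            sign = np.sign(np.dot(emb[:, k], proj[:, k])) or 1.0
            np.testing.assert_allclose(emb[:, k], sign * proj[:, k], atol=1e-8)

    def test_low_dimension_falls_back_to_pca(self):
        points = np.random.default_rng(3).normal(size=(2, 20))
        with pytest.warns(UserWarning, match="falling back to PCA"):
            emb = embed_features(_points_ds(points),
                                 RepresentationSpec(technique="tsne", seed=0))
        assert emb.shape == (2, 2)

    @pytest.mark.parametrize("metric", ["hamming", "mahalanobis", "chebychev", "cosine"])
    def test_tsne_metric_variants_run_and_are_deterministic(self, metric):
        rng = np.random.default_rng(4)
        ds = _points_ds(rng.normal(size=(12, 25)))
        spec = RepresentationSpec(technique="tsne", metric=metric, seed=5)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = embed_features(ds, spec)
            b = embed_features(ds, spec)
        assert a.shape == (12, 2)
        np.testing.assert_array_equal(a, b)

    def test_umap_runs_and_is_deterministic(self):
        rng = np.random.default_rng(5)
        ds = _points_ds(rng.normal(size=(10, 30)))
        spec = RepresentationSpec(technique="umap", seed=6)
        a = embed_features(ds, spec)
        b = embed_features(ds, spec)
        assert a.shape == (10, 2)
        np.testing.assert_array_equal(a, b)


class TestMinAreaRectangle:
    def test_unit_square(self):
        rot, corners = min_area_rectangle(np.array([[0, 0], [1, 0], [1, 1], [0, 1]]))
        assert rect_area(corners) == pytest.approx(1.0)
        assert rot % 90.0 == pytest.approx(0.0, abs=1e-9)

    def test_matches_rotation_sweep_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            points = rng.normal(size=(20, 2))
            _, corners = min_area_rectangle(points)
            assert rect_area(corners) <= sweep_oracle(points) + 1e-9

    def test_never_worse_than_axis_aligned_bbox(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            points = rng.normal(size=(rng.integers(3, 30), 2))
            _, corners = min_area_rectangle(points)
            ext = points.max(axis=0) - points.min(axis=0)
            assert rect_area(corners) <= ext[0] * ext[1] + 1e-9

    def test_rotation_invariance_of_area(self):
        rng = np.random.default_rng(12)
        points = rng.normal(size=(25, 2))
        _, corners = min_area_rectangle(points)
        base = rect_area(corners)
        for deg in (13.7, 45.0, 88.2):
            _, c2 = min_area_rectangle(_rotate(points, deg))
            assert abs(rect_area(c2) - base) < 1e-6 * base

    def test_collinear_points_give_zero_height(self):
        points = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        rot, corners = min_area_rectangle(points)
        assert rect_area(corners) == pytest.approx(0.0, abs=1e-12)
        coords = discretize(points, rot, 10, 10)
        assert len(np.unique(coords[:, 0])) == 1  # downstream grid: one row

    def test_contains_all_points(self):
        rng = np.random.default_rng(13)
        points = rng.normal(size=(30, 2))
        rot, corners = min_area_rectangle(points)
        rp, rc = _rotate(points, rot), _rotate(corners, rot)
        lo, hi = rc.min(axis=0) - 1e-9, rc.max(axis=0) + 1e-9
        assert np.all(rp >= lo) and np.all(rp <= hi)

    def test_agrees_with_shapely(self):
        from shapely.geometry import MultiPoint
        rng = np.random.default_rng(14)
        points = rng.normal(size=(40, 2))
        _, corners = min_area_rectangle(points)
        hull = MultiPoint([tuple(pt) for pt in points]).minimum_rotated_rectangle
        assert rect_area(corners) == pytest.approx(hull.area, rel=1e-9)


class TestDiscretize:
    def test_opposite_corners_anchor_the_grid(self):
        points = np.array([[0.0, 1.0], [1.0, 0.0]])  # top-left and bottom-right
        coords = discretize(points, 0.0, 10, 10)
        np.testing.assert_array_equal(coords, [[0, 0], [9, 9]])

    def test_single_point_lands_at_origin_cell(self):
        coords = discretize(np.array([[3.7, -1.2]]), 0.0, 8, 8)
        np.testing.assert_array_equal(coords, [[0, 0]])

    def test_bounds_and_histogram_oracle(self):
        rng = np.random.default_rng(20)
        points = rng.uniform(size=(1000, 2))
        # anchor the unit square so the affine map matches histogram binning
        points[0], points[1] = (0.0, 0.0), (1.0, 1.0)
        p = q = 50
        coords = discretize(points, 0.0, p, q)
        assert coords.min() >= 0 and coords[:, 0].max() < p and coords[:, 1].max() < q
        hist, _, _ = np.histogram2d(points[:, 0], points[:, 1], bins=[q, p],
                                    range=[[0, 1], [0, 1]])
        assert len(np.unique(coords, axis=0)) == np.count_nonzero(hist)


class TestPixelMap:
    def test_coords_in_bounds_and_deterministic(self, small_ringnorm):
        spec = RepresentationSpec(technique="pca")
        pm1 = compute_pixel_map(small_ringnorm, spec, p=20, q=20)
        pm2 = compute_pixel_map(small_ringnorm, spec, p=20, q=20)
        assert pm1.coords.shape == (20, 2)
        assert pm1.coords.min() >= 0 and pm1.coords.max() < 20
        np.testing.assert_array_equal(pm1.coords, pm2.coords)

    def test_hand_planted_embedding(self, monkeypatch):
        planted = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0], [4.0, 4.0], [2.0, 2.0]])
        import mrepinsight.mapping as mapping
        monkeypatch.setattr(mapping, "embed_features", lambda ds, spec: planted)
        ds = TabularDataset(values=np.zeros((5, 4)) + np.arange(4))
        pm = mapping.compute_pixel_map(ds, RepresentationSpec(technique="pca"), p=4, q=4)
        assert pm.rotation_deg == pytest.approx(0.0)
        np.testing.assert_array_equal(
            pm.coords, [[3, 0], [3, 3], [0, 0], [0, 3], [2, 2]])

    def test_out_of_bounds_coords_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            PixelMap(p=2, q=2, coords=np.array([[0, 2]]), rotation_deg=0.0,
                     spec=RepresentationSpec(technique="pca"))

    def test_json_round_trip(self, tmp_path, small_ringnorm):
        pm = compute_pixel_map(small_ringnorm, RepresentationSpec(technique="pca"),
                               p=16, q=16)
        pm.to_json(tmp_path / "pm.json")
        back = PixelMap.from_json(tmp_path / "pm.json")
        np.testing.assert_array_equal(back.coords, pm.coords)
        assert back.spec == pm.spec
        assert back.rotation_deg == pm.rotation_deg

    def test_representation_diversity(self, small_ringnorm):
        pm_a = compute_pixel_map(small_ringnorm, RepresentationSpec(technique="pca"),
                                 p=20, q=20)
        pm_b = compute_pixel_map(small_ringnorm,
                                 RepresentationSpec(technique="kpca"), p=20, q=20)
        pairs = [(i, j) for i in range(20) for j in range(i + 1, 20)]
        assert any(pixel_distance(pm_a, i, j) != pixel_distance(pm_b, i, j)
                   for i, j in pairs)


class TestPixelDistance:
    def test_identity_symmetry_and_345(self, toy_map):
        assert pixel_distance(toy_map, 1, 1) == 0.0
        assert pixel_distance(toy_map, 0, 2) == pytest.approx(math.hypot(3, 3))
        pm = PixelMap(p=5, q=5, coords=np.array([[0, 0], [3, 4]]), rotation_deg=0.0,
                      spec=RepresentationSpec(technique="pca"))
        assert pixel_distance(pm, 0, 1) == 5.0
        assert pixel_distance(pm, 1, 0) == 5.0

    def test_index_out_of_range(self, toy_map):
        with pytest.raises(IndexError):
            pixel_distance(toy_map, 0, 99)
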