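"""Reference-map tests: embedding, density centers, Voronoi, boundary, k-NN."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from phenotracer import (
    CellMatrix,
    StateLabeling,
    assign_region,
    embed_reference,
    map_boundary,
    state_time_density_centers,
    voronoi_partition,
)
from phenotracer.datatypes import PhenoMap
from phenotracer.phenomap import build_map, load_map, save_map

MARKERS6 = ["E-Cadherin", "Vimentin", "CD44", "CD24", "MUC1", "Twist"]


def two_blob_matrix(rng, n=240, sep=10.0):
    a = rng.normal(0.0, 1.0, (n // 2, 6))
    b = rng.normal(sep, 1.0, (n - n // 2, 6))
    return CellMatrix(np.vstack([a, b]), MARKERS6, transformed=True)


class TestEmbedding:
    def test_separated_blobs_stay_separated(self, rng):
        mat = two_blob_matrix(rng)
        coords = embed_reference(mat, perplexity=30, seed=0)
        half = mat.n_cells // 2
        ca, cb = coords[:half].mean(axis=0), coords[half:].mean(axis=0)
        spread = 0.5 * (
            np.linalg.norm(coords[:half] - ca, axis=1).mean()
            + np.linalg.norm(coords[half:] - cb, axis=1).mean()
        )
        assert np.linalg.norm(ca - cb) > 3.0 * spread

    def test_deterministic_given_seed(self, rng):
        mat = two_blob_matrix(rng, n=150)
        c1 = embed_reference(mat, seed=11)
        c2 = embed_reference(mat, seed=11)
        assert np.array_equal(c1, c2)
        assert np.allclose(c1.mean(axis=0), 0.0, atol=1e-6)

    def test_default_perplexity_is_30(self):
        import inspect

        assert inspect.signature(embed_reference).parameters["perplexity"].default == 30

    def test_too_few_cells_suggests_smaller_perplexity(self, rng):
        mat = CellMatrix(rng.normal(0, 1, (20, 6)), MARKERS6, transformed=True)
        with pytest.raises(ValueError, match="perplexity"):
            embed_reference(mat, perplexity=30)

    def test_requires_six_markers(self, rng):
        mat = CellMatrix(rng.normal(0, 1, (100, 3)), MARKERS6[:3], transformed=True)
        with pytest.raises(ValueError, match="6 marker"):
            embed_reference(mat)


class TestDensityCenters:
    def test_tight_blob_center_near_blob_mean(self, rng):
        pts = rng.normal(5.0, 0.3, (300, 2))
        labeling = StateLabeling(np.ones(300, dtype=int), ["a", "b"], 2)
        labeling.labels[:5] = 2  # a token second state
        centers = state_time_density_centers(
            pts, labeling, np.zeros(300), bin_sizes=(1, 2, 3, 4)
        )
        assert np.linalg.norm(centers[0] - pts[labeling.labels == 1].mean(axis=0)) < 4.0

    def test_single_cell_state_center_is_that_cell(self, rng):
        pts = np.vstack([rng.normal(0, 1, (50, 2)), [[25.0, 25.0]]])
        labels = np.concatenate([np.ones(50, dtype=int), [2]])
        labeling = StateLabeling(labels, ["a", "b"], 2)
        centers = state_time_density_centers(pts, labeling, np.zeros(51))
        assert np.allclose(centers[1], [25.0, 25.0])

    def test_eight_states_give_eight_centers(self, rng):
        pts = rng.normal(0, 5, (800, 2))
        labels = np.repeat(np.arange(1, 9), 100)
        labeling = StateLabeling(labels, [f"S{k}" for k in range(1, 9)], 8)
        times = np.tile(np.repeat([0.0, 2.0], 50), 8)
        centers = state_time_density_centers(pts, labeling, times)
        assert centers.shape == (8, 2)

    def test_peak_time_restriction(self, rng):
        # state 1 peaks at t=2 where its cells sit at (10, 10); the t=0
        # cells at the origin must not attract the center
        pts = np.vstack(
            [rng.normal(0, 0.2, (20, 2)), rng.normal(10, 0.2, (100, 2)),
             rng.normal(-5, 0.2, (200, 2))]
        )
        labels = np.concatenate([np.ones(120, dtype=int), np.full(200, 2)])
        times = np.concatenate([np.zeros(20), np.full(100, 2.0), np.full(200, 0.0)])
        labeling = StateLabeling(labels, ["a", "b"], 2)
        centers = state_time_density_centers(pts, labeling, times)
        assert np.linalg.norm(centers[0] - [10, 10]) < 2.0

    def test_empty_state_names_the_state(self, rng):
        pts = rng.normal(0, 1, (10, 2))
        labeling = StateLabeling(np.ones(10, dtype=int), ["a", "ghost"], 2)
        with pytest.raises(ValueError, match="ghost"):
            state_time_density_centers(pts, labeling, np.zeros(10))


class TestVoronoi:
    def test_two_centers_split_by_bisector(self):
        boundary = Polygon([(-10, -10), (10, -10), (10, 10), (-10, 10)])
        centers = np.array([[-2.0, 0.0], [2.0, 0.0]])
        regions = voronoi_partition(centers, boundary)
        assert regions[0].covers(Point(-5, 3))
        assert regions[1].covers(Point(5, -3))
        # bisector is the y-axis: region areas equal
        assert np.isclose(regions[0].area, regions[1].area)

    def test_membership_matches_nearest_center(self, rng):
        boundary = Polygon([(-5, -5), (5, -5), (5, 5), (-5, 5)])
        centers = rng.uniform(-4, 4, (8, 2))
        regions = voronoi_partition(centers, boundary)
        pts = rng.uniform(-5, 5, (500, 2))
        for p in pts:
            nearest = int(np.argmin(np.linalg.norm(centers - p, axis=1)))
            inside = [i for i, r in enumerate(regions) if r.covers(Point(p))]
            assert nearest in inside

    def test_regions_tile_the_boundary(self, rng):
        boundary = Polygon([(-5, -5), (5, -5), (5, 5), (-5, 5)])
        centers = rng.uniform(-4, 4, (8, 2))
        regions = voronoi_partition(centers, boundary)
        assert np.isclose(sum(r.area for r in regions), boundary.area, rtol=1e-6)
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                inter = regions[i].intersection(regions[j]).area
                assert inter < 1e-9 * boundary.area

    def test_duplicate_centers_rejected(self):
        boundary = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        with pytest.raises(ValueError, match="duplicate"):
            voronoi_partition(np.array([[0.5, 0.5], [0.5, 0.5]]), boundary)


class TestBoundary:
    def test_square_corners_give_the_square(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        poly = map_boundary(pts, alpha=0.1)
        assert np.isclose(poly.area, 1.0)

    def test_half_annulus_concavity_captured(self, rng):
        # a full annulus alpha-shape has a hole, which the simple-polygon
        # contract excludes; the half annulus is concave but hole-free
        theta = rng.uniform(0, np.pi, 2000)
        r = rng.uniform(3.0, 4.0, 2000)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        poly = map_boundary(pts, alpha=1.0)
        hull_area = map_boundary(pts, alpha=1e-9).area
        assert poly.area < 0.75 * hull_area

    def test_all_points_contained_at_auto_alpha(self, rng):
        pts = rng.normal(0, 2, (500, 2))
        poly = map_boundary(pts)
        inside = np.mean([poly.covers(Point(p)) for p in pts])
        assert inside >= 0.99

    def test_bad_alpha_falls_back_to_hull(self, rng):
        pts = np.vstack(
            [rng.normal(0, 0.5, (50, 2)), rng.normal(100, 0.5, (50, 2))]
        )
        with pytest.warns(UserWarning, match="convex hull"):
            poly = map_boundary(pts, alpha=1.0)  # disconnects the two blobs
        hull = map_boundary(pts, alpha=1e-9)
        assert np.isclose(poly.area, hull.area)


def toy_map(rng, K=4):
    centers = rng.uniform(-5, 5, (K, 2))
    boundary = Polygon([(-8, -8), (8, -8), (8, 8), (-8, 8)])
    regions = voronoi_partition(centers, boundary)
    return PhenoMap(
        coords=rng.uniform(-8, 8, (50, 2)),
        centers=centers,
        state_ids=np.arange(1, K + 1),
        regions=regions,
        boundary=boundary,
        state_names=[f"S{k}" for k in range(1, K + 1)],
        marker_names=MARKERS6,
    )


class TestAssignRegion:
    def test_point_at_center_gets_that_state(self, rng):
        m = toy_map(rng)
        ids, out = assign_region(m.centers, m)
        assert np.array_equal(ids, m.state_ids)
        assert not out.any()

    def test_matches_brute_force_nearest_center(self, rng):
        m = toy_map(rng, K=6)
        pts = rng.uniform(-8, 8, (1000, 2))
        ids, _ = assign_region(pts, m)
        brute = np.array(
            [np.argmin(np.linalg.norm(m.centers - p, axis=1)) + 1 for p in pts]
        )
        assert np.array_equal(ids, brute)

    def test_equidistant_tie_goes_to_lower_state_id(self):
        boundary = Polygon([(-4, -4), (4, -4), (4, 4), (-4, 4)])
        centers = np.array([[-1.0, 0.0], [1.0, 0.0]])
        m = PhenoMap(
            coords=np.zeros((3, 2)),
            centers=centers,
            state_ids=np.array([1, 2]),
            regions=voronoi_partition(centers, boundary),
            boundary=boundary,
            state_names=["a", "b"],
            marker_names=MARKERS6,
        )
        ids, _ = assign_region(np.array([[0.0, 2.0]]), m)
        assert ids[0] == 1

    def test_outside_boundary_flagged_but_assigned(self, rng):
        m = toy_map(rng)
        ids, out = assign_region(np.array([[100.0, 100.0]]), m)
        assert out[0] and ids[0] in m.state_ids

    def test_rigid_transform_invariance(self, rng):
        m = toy_map(rng, K=5)
        pts = rng.uniform(-8, 8, (200, 2))
        ids, _ = assign_region(pts, m)
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        shift = np.array([3.0, -2.0])
        boundary2 = Polygon([tuple(R @ np.array(c) + shift)
                             for c in m.boundary.exterior.coords])
        m2 = PhenoMap(
            coords=m.coords @ R.T + shift,
            centers=m.centers @ R.T + shift,
            state_ids=m.state_ids,
            regions=voronoi_partition(m.centers @ R.T + shift, boundary2),
            boundary=boundary2,
            state_names=m.state_names,
            marker_names=m.marker_names,
        )
        ids2, _ = assign_region(pts @ R.T + shift, m2)
        assert np.array_equal(ids, ids2)

    def test_knn_weighting_supported(self, rng):
        m = toy_map(rng, K=5)
        pts = rng.uniform(-8, 8, (50, 2))
        ids, _ = assign_region(pts, m, k=3)
        assert np.all(np.isin(ids, m.state_ids))


def test_build_save_load_round_trip(rng, tmp_path):
    """Full construction from labeled cells, serialized and restored."""
    n = 300
    means = {1: 0.0, 2: 8.0}
    labels = np.concatenate([np.ones(n // 2, dtype=int), np.full(n // 2, 2)])
    X = np.vstack(
        [rng.normal(means[l], 1.0, 6) for l in labels]
    )
    mat = CellMatrix(X, MARKERS6, transformed=True)
    labeling = StateLabeling(labels, ["E-like", "M-like"], 2)
    times = np.tile([0.0, 2.0], n // 2)
    m = build_map(mat, labeling, times, method="pca", seed=0)
    assert len(m.regions) == 2 and len(m.centers) == 2
    save_map(m, tmp_path / "map")
    back = load_map(tmp_path / "map")
    assert np.allclose(back.coords, m.coords)
    assert np.allclose(back.centers, m.centers)
    assert back.state_names == m.state_names
    assert np.isclose(back.boundary.area, m.boundary.area)
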