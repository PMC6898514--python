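"""Segmented 2D reference map construction (embedding, centers, regions).

The reference map is built from labeled reference cells in four steps:

1. a 2D stochastic-neighbor embedding of the six clustering markers
   (perplexity 30 by default);
2. one center per state, placed at the centroid of the densest square bin
   of that state's cells at its peak time point, with the bin side chosen
   over candidate sizes 1..8 map units by the largest adjacent change in
   densest-bin occupancy;
3. a Voronoi partition of the map around the centers, clipped to
4. an alpha-shape boundary of the embedded cloud (a "generalized convex
   hull" from the Delaunay triangulation, falling back to the convex hull
   when the alpha-shape would be disconnected).

New points are assigned to states by nearest center (k = 1), which for
interior points coincides with Voronoi-cell membership.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import unary_union

from .datatypes import CellMatrix, PhenoMap, StateLabeling

DEFAULT_PERPLEXITY = 30.0
DEFAULT_BIN_SIZES = tuple(range(1, 9))


def embed_reference(
    matrix: CellMatrix,
    perplexity: float = DEFAULT_PERPLEXITY,
    seed: int = 0,
    method: str = "tsne",
) -> np.ndarray:
    """2D embedding of the six clustering markers, centered at the origin.

    ``method="tsne"`` (default) uses t-SNE with a fixed seed and PCA
    initialization, which is deterministic for a given input order;
    ``method="pca"`` is a fast deterministic alternative satisfying the
    same contract (useful for tests and quick runs).
    """
    X = matrix.values
    if X.shape[1] != 6:
        raise ValueError(f"expected exactly 6 marker columns, got {X.shape[1]}")
    if method == "tsne":
        if X.shape[0] < 3 * perplexity:
            raise ValueError(
                f"{X.shape[0]} cells cannot support perplexity {perplexity}; "
                f"use perplexity <= {X.shape[0] / 3:.0f}"
            )
        from sklearn.manifold import TSNE

        coords = TSNE(
            n_components=2,
            perplexity=perplexity,
            init="pca",
            random_state=seed,
            n_jobs=1,
        ).fit_transform(X)
    elif method == "pca":
        from sklearn.decomposition import PCA

        coords = PCA(n_components=2, random_state=seed).fit_transform(X)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    coords = np.asarray(coords, dtype=float)
    return coords - coords.mean(axis=0)


def _densest_bin(pts: np.ndarray, size: float) -> tuple[int, tuple[int, int]]:
    """Occupancy and index of the densest square bin of side ``size``.

    The grid is anchored at the point-cloud minimum; ties go to the
    lexicographically smallest bin index.
    """
    ij = np.floor((pts - pts.min(axis=0)) / size).astype(int)
    order = np.lexsort((ij[:, 1], ij[:, 0]))
    ij_sorted = ij[order]
    uniq, counts = np.unique(ij_sorted, axis=0, return_counts=True)
    best = int(np.argmax(counts))  # first max = lexicographically smallest
    return int(counts[best]), (int(uniq[best, 0]), int(uniq[best, 1]))


def state_time_density_centers(
    coords: np.ndarray,
    labeling: StateLabeling,
    time_label: np.ndarray,
    bin_sizes: tuple[int, ...] = DEFAULT_BIN_SIZES,
) -> np.ndarray:
    """One map center per state from its densest time-dependent bin.

    For each state, cells are restricted to the state's peak time point
    (the time with maximal state fraction). The map is gridded at each
    candidate bin side; the side whose densest-bin occupancy shows the
    largest absolute change relative to the previous candidate is chosen
    (the larger side of the pair; ties resolved to the smaller side), and
    the center is the centroid of the cells in that densest bin.
    """
    coords = np.asarray(coords, dtype=float)
    time_label = np.asarray(time_label, dtype=float)
    if coords.shape[0] != labeling.n_cells or time_label.shape[0] != labeling.n_cells:
        raise ValueError("coords, labels and time labels must align")
    if len(bin_sizes) < 2:
        raise ValueError("need at least two candidate bin sizes")
    times = np.unique(time_label)
    centers = np.empty((labeling.K, 2))
    for k in range(1, labeling.K + 1):
        in_state = labeling.labels == k
        if not in_state.any():
            raise ValueError(f"state {labeling.state_names[k - 1]!r} has no cells")
        # peak time point: maximal share of that time point's cells
        fracs = [
            in_state[time_label == t].mean() for t in times
        ]
        peak = times[int(np.argmax(fracs))]
        pts = coords[in_state & (time_label == peak)]
        if pts.shape[0] == 0:  # pragma: no cover - argmax guarantees > 0
            raise ValueError(
                f"state {labeling.state_names[k - 1]!r} empty at its peak time"
            )
        occ = [_densest_bin(pts, float(s))[0] for s in bin_sizes]
        changes = np.abs(np.diff(occ))
        i = int(np.argmax(changes))  # ties: argmax picks the smaller pair
        chosen = float(bin_sizes[i + 1])
        _, bin_idx = _densest_bin(pts, chosen)
        ij = np.floor((pts - pts.min(axis=0)) / chosen).astype(int)
        members = pts[(ij[:, 0] == bin_idx[0]) & (ij[:, 1] == bin_idx[1])]
        centers[k - 1] = members.mean(axis=0)
    return centers


def _halfplane_toward(c_k: np.ndarray, c_j: np.ndarray, radius: float) -> Polygon:
    """Polygon approximating the half-plane of points closer to c_k than c_j."""
    d = c_j - c_k
    norm = np.linalg.norm(d)
    d = d / norm
    perp = np.array([-d[1], d[0]])
    mid = (c_k + c_j) / 2.0
    corners = [
        mid + perp * radius,
        mid - perp * radius,
        mid - perp * radius - d * 2 * radius,
        mid + perp * radius - d * 2 * radius,
    ]
    return Polygon(corners)


def voronoi_partition(centers: np.ndarray, boundary: Polygon) -> list[Polygon]:
    """Voronoi cells of the centers, clipped to the boundary polygon.

    Each region is the intersection of the boundary with the half-planes
    closer to its center than to every other center, so regions tile the
    boundary exactly (up to floating-point sliver area).
    """
    centers = np.asarray(centers, dtype=float)
    if len(centers) < 2:
        raise ValueError("need at least 2 centers")
    uniq = np.unique(centers, axis=0)
    if uniq.shape[0] != centers.shape[0]:
        raise ValueError("duplicate centers")
    minx, miny, maxx, maxy = boundary.bounds
    radius = 4.0 * max(maxx - minx, maxy - miny, 1.0) + float(
        np.abs(centers).max()
    )
    regions = []
    for k, c_k in enumerate(centers):
        region = boundary
        for j, c_j in enumerate(centers):
            if j == k:
                continue
            region = region.intersection(_halfplane_toward(c_k, c_j, radius))
        regions.append(region)
    return regions


def _triangle_circumradius(pts: np.ndarray) -> float:
    a = np.linalg.norm(pts[1] - pts[0])
    b = np.linalg.norm(pts[2] - pts[1])
    c = np.linalg.norm(pts[0] - pts[2])
    area2 = abs(
        (pts[1][0] - pts[0][0]) * (pts[2][1] - pts[0][1])
        - (pts[2][0] - pts[0][0]) * (pts[1][1] - pts[0][1])
    )
    if area2 <= 0:
        return np.inf
    return a * b * c / (2.0 * area2)


def map_boundary(
    coords: np.ndarray, alpha: float | None = None, min_contained: float = 0.99
) -> Polygon:
    """Alpha-shape boundary of the embedded cloud as a simple polygon.

    Triangles of the Delaunay triangulation with circumradius <= 1/alpha
    are kept and unioned; as alpha -> 0 this converges to the convex hull.
    If ``alpha`` is None it is chosen automatically as the largest value
    (over circumradius quantiles) yielding a connected, hole-free shape
    containing at least ``min_contained`` of the points. A disconnected
    result falls back to the convex hull with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 points")
    tri = Delaunay(coords)
    radii = np.array(
        [_triangle_circumradius(coords[s]) for s in tri.simplices]
    )
    hull = MultiPoint([tuple(p) for p in coords]).convex_hull

    def shape_for(alpha_val: float):
        keep = radii <= 1.0 / alpha_val
        if not keep.any():
            return None
        polys = [Polygon(coords[s]) for s in tri.simplices[keep]]
        merged = unary_union(polys)
        if merged.geom_type != "Polygon" or merged.interiors:
            return None
        inside = np.array(
            [merged.covers(Point(p)) for p in coords]
        )
        if inside.mean() < min_contained:
            return None
        return Polygon(merged.exterior)

    if alpha is not None:
        shape = shape_for(alpha)
        if shape is None:
            warnings.warn(
                "alpha-shape disconnected or too exclusive; falling back to "
                "the convex hull"
            )
            return Polygon(hull)
        return shape
    finite = radii[np.isfinite(radii)]
    for q in (0.90, 0.95, 0.99, 1.0):
        cand = 1.0 / float(np.quantile(finite, q))
        shape = shape_for(cand)
        if shape is not None:
            return shape
    return Polygon(hull)


def build_map(
    matrix: CellMatrix,
    labeling: StateLabeling,
    time_label: np.ndarray,
    perplexity: float = DEFAULT_PERPLEXITY,
    bin_sizes: tuple[int, ...] = DEFAULT_BIN_SIZES,
    alpha: float | None = None,
    seed: int = 0,
    method: str = "tsne",
) -> PhenoMap:
    """Full map construction: embed, place centers, segment, bound."""
    coords = embed_reference(matrix, perplexity=perplexity, seed=seed, method=method)
    centers = state_time_density_centers(coords, labeling, time_label, bin_sizes)
    boundary = map_boundary(coords, alpha=alpha)
    regions = voronoi_partition(centers, boundary)
    return PhenoMap(
        coords=coords,
        centers=centers,
        state_ids=np.arange(1, labeling.K + 1),
        regions=regions,
        boundary=boundary,
        state_names=list(labeling.state_names),
        marker_names=list(matrix.marker_names),
        embedding_params={"perplexity": perplexity, "seed": seed, "method": method},
    )


def assign_region(
    points: np.ndarray, pheno_map: PhenoMap, k: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each point to a state by k-NN on the partition centers.

    With the default k=1 this is nearest-center assignment, identical to
    Voronoi membership for points inside the boundary; ties go to the
    lower state id. k > 1 uses inverse-distance weighting over the k
    nearest centers. Points outside the boundary are still assigned but
    flagged in the returned ``out_of_map`` mask.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    centers = pheno_map.centers
    d = np.linalg.norm(points[:, None, :] - centers[None], axis=2)
    if k <= 1:
        choice = np.argmin(d, axis=1)  # first (lowest id) wins ties
    else:
        k = min(k, centers.shape[0])
        nearest = np.argsort(d, axis=1)[:, :k]
        w = 1.0 / (np.take_along_axis(d, nearest, axis=1) + 1e-12)
        scores = np.zeros((points.shape[0], centers.shape[0]))
        for i in range(points.shape[0]):
            np.add.at(scores[i], nearest[i], w[i])
        choice = np.argmax(scores, axis=1)
    state_ids = pheno_map.state_ids[choice]
    out = np.array([not pheno_map.boundary.covers(Point(p)) for p in points])
    return state_ids, out


# ---------------------------------------------------------------------------
# Serialization: a directory of delimited tables and JSON polygons


def save_map(pheno_map: PhenoMap, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(pheno_map.coords, columns=["x", "y"]).to_csv(
        d / "coords.csv", index=False
    )
    centers = pd.DataFrame(pheno_map.centers, columns=["x", "y"])
    centers.insert(0, "state_id", pheno_map.state_ids)
    centers.insert(1, "state", pheno_map.state_names)
    centers.to_csv(d / "centers.csv", index=False)
    geo = {
        "boundary": list(map(list, pheno_map.boundary.exterior.coords)),
        "regions": [
            list(map(list, r.exterior.coords)) if not r.is_empty else []
            for r in pheno_map.regions
        ],
        "marker_names": pheno_map.marker_names,
        "state_names": pheno_map.state_names,
        "embedding_params": pheno_map.embedding_params,
    }
    (d / "geometry.json").write_text(json.dumps(geo))


def load_map(directory) -> PhenoMap:
    d = Path(directory)
    coords = pd.read_csv(d / "coords.csv").to_numpy()
    centers_df = pd.read_csv(d / "centers.csv")
    geo = json.loads((d / "geometry.json").read_text())
    return PhenoMap(
        coords=coords,
        centers=centers_df[["x", "y"]].to_numpy(),
        state_ids=centers_df["state_id"].to_numpy(),
        regions=[Polygon(r) if r else Polygon() for r in geo["regions"]],
        boundary=Polygon(geo["boundary"]),
        state_names=geo["state_names"],
        marker_names=geo["marker_names"],
        embedding_params=geo["embedding_params"],
    )
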