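"""Feature-to-pixel mapping: the DeepInsight transform ``P = H(M)``.

Each representation embeds the *features* (rows of the training matrix) into
the plane with a manifold technique, encloses the point cloud in its
minimum-area rotated rectangle (rotating calipers over the convex hull),
aligns the rectangle with the axes, and discretizes the rotated coordinates
onto a ``p x q`` pixel grid.  The result is a frozen :class:`PixelMap`
assigning every feature ``i`` a pixel ``[a_i, b_i]``; it is computed once on
training data and reused verbatim at test time.

Distinct representations (different manifold technique, distance metric, or
enhancement filter) place the same feature at different pixels, so the
inter-feature pixel distance ``D_r`` varies across representations — the
premise that lets an ensemble over representations see complementary
spatial arrangements of the same data.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .data import TabularDataset

__all__ = [
    "RepresentationSpec",
    "PixelMap",
    "embed_features",
    "min_area_rectangle",
    "discretize",
    "compute_pixel_map",
    "pixel_distance",
]

_TECHNIQUES = {"tsne", "umap", "pca", "kpca"}
_TSNE_METRICS = {"euclidean", "cosine", "hamming", "chebychev", "chebyshev", "mahalanobis"}
_FILTERS = {"none", "blur", "gabor"}


@dataclass(frozen=True)
class RepresentationSpec:
    """One tabular-to-image recipe: manifold technique + metric + filter.

    ``metric`` is only meaningful for t-SNE (the other techniques define
    their own geometry).  ``filter`` is an image-domain enhancement applied
    after rendering.  ``params`` holds technique-specific settings such as
    ``perplexity``, ``n_neighbors``, ``kernel``, ``sigma`` (blur) or
    ``frequencies``/``n_orientations`` (Gabor bank).
    """

    technique: str = "tsne"
    metric: str | None = None
    filter: str = "none"
    params: dict = field(default_factory=dict, hash=False)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.technique not in _TECHNIQUES:
            raise ValueError(f"unknown technique {self.technique!r}; choose from {sorted(_TECHNIQUES)}")
        if self.metric is not None:
            if self.technique != "tsne":
                raise ValueError("metric may only be set for technique='tsne'")
            if self.metric not in _TSNE_METRICS:
                raise ValueError(f"unknown t-SNE metric {self.metric!r}")
        if self.filter == "assignment":
            raise NotImplementedError(
                "the assignment-distribution enhancement is not implemented; "
                "choose filter in {'none', 'blur', 'gabor'}"
            )
        if self.filter not in _FILTERS:
            raise ValueError(f"unknown filter {self.filter!r}; choose from {sorted(_FILTERS)}")

    @property
    def name(self) -> str:
        label = self.technique
        if self.metric is not None:
            label += f" ({self.metric})"
        if self.filter != "none":
            label += f" + {self.filter}"
        return label

    def to_dict(self) -> dict:
        return {"technique": self.technique, "metric": self.metric,
                "filter": self.filter, "params": dict(self.params), "seed": self.seed}

    @classmethod
    def from_dict(cls, payload: dict) -> "RepresentationSpec":
        return cls(technique=payload["technique"], metric=payload.get("metric"),
                   filter=payload.get("filter", "none"),
                   params=dict(payload.get("params", {})), seed=payload.get("seed", 0))


@dataclass
class PixelMap:
    """Frozen per-feature pixel coordinates on a ``p x q`` grid.

    ``coords[i] = [a_i, b_i]`` with row ``a_i`` in ``[0, p)`` and column
    ``b_i`` in ``[0, q)`` (top-left origin, half-open cells).
    ``rotation_deg`` is the alignment rotation applied to the raw embedding,
    which is retained for diagnostics.
    """

    p: int
    q: int
    coords: np.ndarray
    rotation_deg: float
    spec: RepresentationSpec
    embedding: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must have shape (d, 2)")
        if self.p < 1 or self.q < 1:
            raise ValueError("grid dimensions must be >= 1")
        a, b = self.coords[:, 0], self.coords[:, 1]
        if len(a) and ((a < 0).any() or (a >= self.p).any() or (b < 0).any() or (b >= self.q).any()):
            raise ValueError("pixel coordinates out of grid bounds")

    @property
    def n_features(self) -> int:
        return len(self.coords)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "p": self.p, "q": self.q,
            "coords": self.coords.tolist(),
            "rotation_deg": self.rotation_deg,
            "spec": self.spec.to_dict(),
            "embedding": None if self.embedding is None else np.asarray(self.embedding).tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PixelMap":
        payload = json.loads(Path(path).read_text())
        emb = payload.get("embedding")
        return cls(p=payload["p"], q=payload["q"], coords=np.asarray(payload["coords"]),
                   rotation_deg=payload["rotation_deg"],
                   spec=RepresentationSpec.from_dict(payload["spec"]),
                   embedding=None if emb is None else np.asarray(emb))


def _hamming_distances(points: np.ndarray) -> np.ndarray:
    """Pairwise hamming distances after binarizing each point at its median."""
    med = np.median(points, axis=1, keepdims=True)
    binary = (points > med).astype(float)
    from scipy.spatial.distance import pdist, squareform
    if points.shape[0] < 2:
        return np.zeros((points.shape[0],) * 2)
    return squareform(pdist(binary, metric="hamming"))


def _mahalanobis_distances(points: np.ndarray, ridge: float) -> np.ndarray:
    """Pairwise Mahalanobis distances with a ridge-regularized covariance.

    Uses the Woodbury identity so only a (d x d) system is solved even when
    the ambient dimension n is large: with Y the centered points,
    (eps*I + Y'Y/(d-1))^-1 applied to differences y_i - y_j reduces to
    Euclidean distances corrected by the d x d Gram matrix.
    """
    d, n = points.shape  # d points in n-dimensional space
    Y = points - points.mean(axis=0, keepdims=True)
    denom = max(d - 1, 1)
    gram = Y @ Y.T  # (d, d)
    eps = ridge
    B = np.linalg.inv(eps * denom * np.eye(d) + gram)
    # ||v||_VI^2 = (1/eps) (||v||^2 - u' B u), u = Y v = gram_i - gram_j
    sq = np.sum(Y ** 2, axis=1)
    euclid2 = sq[:, None] + sq[None, :] - 2 * gram
    U = gram[:, None, :] - gram[None, :, :]  # (d, d, d): U[i,j] = gram_i - gram_j
    corr = np.einsum("ijk,kl,ijl->ij", U, B, U)
    out = (euclid2 - corr) / eps
    np.clip(out, 0.0, None, out=out)
    return np.sqrt(out)


def embed_features(ds: TabularDataset, spec: RepresentationSpec) -> np.ndarray:
    """Embed the ``d`` features of the (training) matrix into the plane.

    The transpose of ``M`` is embedded, i.e. each feature becomes one
    observation with ``n`` coordinates.  Deterministic given ``spec.seed``.
    Returns an array of shape ``(d, 2)``.
    """
    points = np.asarray(ds.values, dtype=float)  # (d, n): features as observations
    d = points.shape[0]
    technique = spec.technique
    if technique in {"tsne", "umap"} and d < 3:
        warnings.warn(
            f"{technique} needs at least 3 features; falling back to PCA", stacklevel=2
        )
        technique = "pca"

    if technique == "pca":
        from sklearn.decomposition import PCA
        n_comp = min(2, d, points.shape[1])
        emb = PCA(n_components=n_comp, svd_solver="full").fit_transform(points)
        if emb.shape[1] < 2:
            emb = np.hstack([emb, np.zeros((d, 2 - emb.shape[1]))])
        return emb

    if technique == "kpca":
        from sklearn.decomposition import KernelPCA
        kernel = spec.params.get("kernel", "rbf")
        gamma = spec.params.get("gamma")
        emb = KernelPCA(n_components=2, kernel=kernel, gamma=gamma,
                        random_state=spec.seed).fit_transform(points)
        return emb

    if technique == "umap":
        import umap
        n_neighbors = int(spec.params.get("n_neighbors", min(15, d - 1)))
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*n_jobs.*")
            warnings.filterwarnings("ignore", message=".*not using the.*")
            reducer = umap.UMAP(n_components=2, n_neighbors=max(2, n_neighbors),
                                min_dist=float(spec.params.get("min_dist", 0.1)),
                                random_state=spec.seed)
            return np.asarray(reducer.fit_transform(points), dtype=float)

    # t-SNE
    from sklearn.manifold import TSNE
    metric = spec.metric or "euclidean"
    perplexity = float(spec.params.get("perplexity", min(30.0, (d - 1) / 3)))
    perplexity = min(max(perplexity, 0.5), d - 1.5) if d > 2 else 0.5
    method = spec.params.get("tsne_method", "exact" if d < 2000 else "barnes_hut")
    common = dict(n_components=2, perplexity=perplexity, random_state=spec.seed,
                  method=method, max_iter=int(spec.params.get("max_iter", 1000)))
    if metric == "hamming":
        dist = _hamming_distances(points)
        tsne = TSNE(metric="precomputed", init="random", **common)
        return np.asarray(tsne.fit_transform(dist), dtype=float)
    if metric == "mahalanobis":
        if points.shape[1] >= d:
            # d points cannot span an n-dimensional covariance: always regularize
            warnings.warn("mahalanobis covariance is singular; using ridge regularization",
                          stacklevel=2)
        dist = _mahalanobis_distances(points, ridge=float(spec.params.get("ridge", 1e-3)))
        tsne = TSNE(metric="precomputed", init="random", **common)
        return np.asarray(tsne.fit_transform(dist), dtype=float)
    if metric == "chebychev":
        metric = "chebyshev"
    tsne = TSNE(metric=metric, init="pca", **common)
    return np.asarray(tsne.fit_transform(points), dtype=float)


def _rotate(points: np.ndarray, deg: float) -> np.ndarray:
    rad = math.radians(deg)
    c, s = math.cos(rad), math.sin(rad)
    R = np.array([[c, -s], [s, c]])
    return points @ R.T


def min_area_rectangle(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Minimum-area enclosing rectangle via rotating calipers over hull edges.

    Returns ``(rotation_deg, corners)`` where rotating the points by
    ``rotation_deg`` (counterclockwise) makes the optimal rectangle
    axis-parallel, and ``corners`` are the rectangle's four corners in the
    original frame.  The optimal rectangle has one side collinear with a
    convex-hull edge, so only hull-edge orientations need to be examined.
    Rotation is reported in ``[0, 90)``; among equal-area candidates the
    smallest non-negative angle wins.  Degenerate inputs (single point,
    collinear set) yield a zero-area rectangle aligned with the principal
    direction.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 1:
        raise ValueError("need at least one point")
    uniq = np.unique(points, axis=0)
    if len(uniq) == 1:
        pt = uniq[0]
        return 0.0, np.tile(pt, (4, 1))

    def _bbox_corners(rot_deg: float) -> np.ndarray:
        rp = _rotate(points, rot_deg)
        lo, hi = rp.min(axis=0), rp.max(axis=0)
        corners = np.array([[lo[0], lo[1]], [hi[0], lo[1]], [hi[0], hi[1]], [lo[0], hi[1]]])
        return _rotate(corners, -rot_deg)

    try:
        hull = ConvexHull(uniq)
        vertices = uniq[hull.vertices]
    except QhullError:
        # collinear: align the principal direction with the x-axis so the
        # zero-extent axis is the height (downstream grid gets one row)
        centered = uniq - uniq.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        angle = math.degrees(math.atan2(vt[0, 1], vt[0, 0]))
        rot = (-angle) % 180.0
        return rot, _bbox_corners(rot)

    best_area, best_rot = math.inf, 0.0
    k = len(vertices)
    for i in range(k):
        edge = vertices[(i + 1) % k] - vertices[i]
        angle = math.degrees(math.atan2(edge[1], edge[0]))
        rot = (-angle) % 90.0
        rp = _rotate(vertices, rot)
        extent = rp.max(axis=0) - rp.min(axis=0)
        area = float(extent[0] * extent[1])
        tol = 1e-12 * max(area, best_area if math.isfinite(best_area) else area, 1e-300)
        if area < best_area - tol:
            best_area, best_rot = area, rot
        elif abs(area - best_area) <= tol and rot < best_rot:
            best_rot = rot
    return best_rot, _bbox_corners(best_rot)


def discretize(points: np.ndarray, rotation_deg: float, p: int, q: int) -> np.ndarray:
    """Affine-map rotated points onto a ``p x q`` grid of half-open cells.

    The rotated bounding rectangle is scaled isotropically (aspect ratio
    preserved; the short axis is letterboxed/centered) and floor-quantized.
    Rows count from the top: the maximum rotated ``y`` lands in row 0.
    Degenerate extents collapse to index 0 along that axis.
    """
    if p < 1 or q < 1:
        raise ValueError("grid dimensions must be >= 1")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    rp = _rotate(points, rotation_deg)
    x, y = rp[:, 0], rp[:, 1]
    w = float(x.max() - x.min()) if len(x) else 0.0
    h = float(y.max() - y.min()) if len(y) else 0.0
    coords = np.zeros((len(points), 2), dtype=int)
    scales = [q / w if w > 0 else np.inf, p / h if h > 0 else np.inf]
    s = min(scales)
    if not np.isfinite(s):
        return coords  # single point (or all coincident): pixel (0, 0)
    if w > 0:
        off_b = (q - w * s) / 2.0
        b = np.floor((x - x.min()) * s + off_b).astype(int)
        coords[:, 1] = np.clip(b, 0, q - 1)
    if h > 0:
        off_a = (p - h * s) / 2.0
        a = np.floor((y.max() - y) * s + off_a).astype(int)
        coords[:, 0] = np.clip(a, 0, p - 1)
    return coords


def compute_pixel_map(ds: TabularDataset, spec: RepresentationSpec,
                      p: int = 50, q: int = 50) -> PixelMap:
    """Full transform ``P = H(M)``: embed, align, discretize.

    Must be called on the training partition only; the resulting map is
    reused verbatim for validation and test samples.
    """
    embedding = embed_features(ds, spec)
    rotation_deg, _ = min_area_rectangle(embedding)
    coords = discretize(embedding, rotation_deg, p, q)
    return PixelMap(p=p, q=q, coords=coords, rotation_deg=rotation_deg,
                    spec=spec, embedding=embedding)


def pixel_distance(pixel_map: PixelMap, i: int, j: int) -> float:
    """Euclidean pixel distance ``D_r`` between features ``i`` and ``j``."""
    d = pixel_map.n_features
    for idx in (i, j):
        if not (0 <= idx < d):
            raise IndexError(f"feature index {idx} out of range [0, {d})")
    diff = pixel_map.coords[i] - pixel_map.coords[j]
    return float(np.hypot(*diff))
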