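"""Synthetic benchmark generators.

Three families are provided:

* ``ringnorm`` — the 20-dimensional two-class Gaussian benchmark in which
  class 1 is drawn from N(0, 4I) and class 2 from N((2/sqrt(d))*1, I).  The
  Bayes-optimal boundary is quadratic (a ring), which makes the problem hard
  for linear classifiers and easy for tree ensembles.
* ``madelon_style`` — clusters on hypercube vertices in a small informative
  subspace, plus exactly-redundant linear combinations and pure-noise
  irrelevant features, with the feature order shuffled (permutation recorded
  in metadata).
* ``gaussian_blobs`` — isotropic Gaussian clusters, one per class; a tiny
  separable fixture for fast pipeline tests.

All generators are deterministic given ``GeneratorConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import TabularDataset

__all__ = [
    "GeneratorConfig",
    "generate",
    "generate_ringnorm",
    "generate_madelon_style",
    "generate_blobs",
]

_FAMILIES = {"ringnorm", "madelon_style", "gaussian_blobs"}


@dataclass
class GeneratorConfig:
    """Configuration shared by all generator families.

    ``class_fractions`` must lie in (0, 1] and sum to 1; class ``k`` receives
    ``ceil(fraction_k * n)`` samples for all but the last class, which takes
    the remainder (so counts always sum to ``n_samples``).
    Family-specific knobs go in ``params``:

    * madelon_style: ``n_informative`` (5), ``n_redundant`` (5),
      ``n_clusters_per_class`` (2), ``class_sep`` (2.0), ``flip_y`` (0.01),
      ``noise_std`` (1.0)
    * gaussian_blobs: ``separation`` (10.0), ``std`` (1.0)
    """

    n_samples: int = 7400
    n_features: int = 20
    class_fractions: tuple[float, ...] = (0.5, 0.5)
    seed: int = 0
    family: str = "ringnorm"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError(f"n_samples must be >= 0, got {self.n_samples}")
        if self.n_features < 1:
            raise ValueError(f"n_features must be >= 1, got {self.n_features}")
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {sorted(_FAMILIES)}")
        fr = np.asarray(self.class_fractions, dtype=float)
        if len(fr) < 2:
            raise ValueError("need at least two classes")
        if (fr <= 0).any() or (fr > 1).any():
            raise ValueError("class fractions must lie in (0, 1]")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {fr.sum()!r}")

    def class_counts(self) -> np.ndarray:
        """Per-class sample counts under the ceil-then-remainder rounding rule."""
        fr = np.asarray(self.class_fractions, dtype=float)
        counts = np.zeros(len(fr), dtype=int)
        remaining = self.n_samples
        for k in range(len(fr) - 1):
            counts[k] = min(math.ceil(fr[k] * self.n_samples), remaining)
            remaining -= counts[k]
        counts[-1] = remaining
        return counts


def _finalize(X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
              metadata: dict) -> TabularDataset:
    """Shuffle sample order and wrap into a feature-major dataset."""
    order = rng.permutation(len(y))
    metadata = dict(metadata)
    metadata["sample_order"] = order.tolist()
    return TabularDataset(values=X[order].T, labels=y[order], metadata=metadata)


def generate_ringnorm(config: GeneratorConfig) -> TabularDataset:
    """Two multivariate Gaussians: class 1 ~ N(0, 4I), class 2 ~ N((2/sqrt(d))1, I)."""
    if config.family != "ringnorm":
        raise ValueError(f"config.family is {config.family!r}, expected 'ringnorm'")
    if len(config.class_fractions) != 2:
        raise ValueError("ringnorm is a two-class problem")
    d = config.n_features
    n1, n2 = config.class_counts()
    rng = np.random.default_rng(config.seed)
    x1 = rng.normal(loc=0.0, scale=2.0, size=(n1, d))
    mu2 = 2.0 / math.sqrt(d)
    x2 = rng.normal(loc=mu2, scale=1.0, size=(n2, d))
    X = np.vstack([x1, x2])
    y = np.concatenate([np.ones(n1, dtype=int), np.full(n2, 2, dtype=int)])
    meta = {"family": "ringnorm", "seed": config.seed, "class2_mean": mu2,
            "class1_var": 4.0, "class2_var": 1.0}
    return _finalize(X, y, rng, meta)


def generate_madelon_style(config: GeneratorConfig) -> TabularDataset:
    """Nonlinear benchmark with informative, exactly-redundant and noise features.

    Informative features place per-class clusters on hypercube vertices
    (side ``2*class_sep``); redundant features are exact linear combinations
    of the informative block (before optional observation noise); remaining
    features are standard-normal noise.  A fraction ``flip_y`` of labels is
    flipped.  The applied feature permutation, cluster centers and mixing
    matrix are recorded in ``metadata``.
    """
    if config.family != "madelon_style":
        raise ValueError(f"config.family is {config.family!r}, expected 'madelon_style'")
    p = config.params
    n_inf = int(p.get("n_informative", 5))
    n_red = int(p.get("n_redundant", 5))
    n_irr = int(p.get("n_irrelevant", config.n_features - n_inf - n_red))
    if n_inf + n_red + n_irr != config.n_features:
        raise ValueError(
            f"informative ({n_inf}) + redundant ({n_red}) + irrelevant ({n_irr}) "
            f"!= n_features ({config.n_features})"
        )
    if n_inf < 1 and (n_red > 0):
        raise ValueError("redundant features require at least one informative feature")
    k_per_class = int(p.get("n_clusters_per_class", 2))
    sep = float(p.get("class_sep", 2.0))
    flip_y = float(p.get("flip_y", 0.01))
    noise_std = float(p.get("noise_std", 1.0))
    c = len(config.class_fractions)
    counts = config.class_counts()
    rng = np.random.default_rng(config.seed)

    n_clusters = c * k_per_class
    if n_inf > 0:
        n_vertices = 2 ** n_inf
        if n_clusters > n_vertices:
            raise ValueError("more clusters than hypercube vertices; raise n_informative")
        vertex_ids = rng.choice(n_vertices, size=n_clusters, replace=False)
        bits = ((vertex_ids[:, None] >> np.arange(n_inf)) & 1) * 2.0 - 1.0
        centers = bits * sep  # (n_clusters, n_inf)
    else:
        centers = np.zeros((n_clusters, 0))
    mixing = rng.normal(size=(n_inf, n_red))

    rows, labels = [], []
    for k, n_k in enumerate(counts):
        cluster_ids = rng.integers(0, k_per_class, size=n_k)
        center = centers[k * k_per_class + cluster_ids]
        informative = center + noise_std * rng.normal(size=(n_k, n_inf))
        redundant = informative @ mixing
        irrelevant = rng.normal(size=(n_k, n_irr))
        rows.append(np.hstack([informative, redundant, irrelevant]))
        labels.append(np.full(n_k, k + 1, dtype=int))
    X = np.vstack(rows) if rows else np.zeros((0, config.n_features))
    y = np.concatenate(labels) if labels else np.zeros(0, dtype=int)

    n_flip = int(round(flip_y * len(y)))
    flip_idx = rng.choice(len(y), size=n_flip, replace=False) if n_flip else np.array([], int)
    for j in flip_idx:
        others = [k + 1 for k in range(c) if k + 1 != y[j]]
        y[j] = others[rng.integers(0, len(others))]

    perm = rng.permutation(config.n_features)
    X = X[:, perm]
    meta = {
        "family": "madelon_style", "seed": config.seed,
        "feature_permutation": perm.tolist(),
        "n_informative": n_inf, "n_redundant": n_red, "n_irrelevant": n_irr,
        "centers": centers.tolist(), "mixing": mixing.tolist(),
        "flipped": np.sort(flip_idx).tolist(), "class_sep": sep,
    }
    return _finalize(X, y, rng, meta)


def generate_blobs(config: GeneratorConfig) -> TabularDataset:
    """Isotropic Gaussian clusters, one per class, centers ``separation`` apart."""
    if config.family != "gaussian_blobs":
        raise ValueError(f"config.family is {config.family!r}, expected 'gaussian_blobs'")
    sep = float(config.params.get("separation", 10.0))
    std = float(config.params.get("std", 1.0))
    c = len(config.class_fractions)
    d = config.n_features
    counts = config.class_counts()
    rng = np.random.default_rng(config.seed)
    # deterministic centers: class k offset along axis k (mod d)
    centers = np.zeros((c, d))
    for k in range(c):
        centers[k, k % d] = sep * (1 + k // d)
    rows, labels = [], []
    for k, n_k in enumerate(counts):
        rows.append(centers[k] + std * rng.normal(size=(n_k, d)))
        labels.append(np.full(n_k, k + 1, dtype=int))
    X = np.vstack(rows) if rows else np.zeros((0, d))
    y = np.concatenate(labels) if labels else np.zeros(0, dtype=int)
    meta = {"family": "gaussian_blobs", "seed": config.seed,
            "centers": centers.tolist(), "std": std, "separation": sep}
    return _finalize(X, y, rng, meta)


def generate(config: GeneratorConfig) -> TabularDataset:
    """Dispatch on ``config.family``."""
    return {
        "ringnorm": generate_ringnorm,
        "madelon_style": generate_madelon_style,
        "gaussian_blobs": generate_blobs,
    }[config.family](config)
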