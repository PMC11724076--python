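"""Dataset container, delimited-text I/O, stratified splitting and normalization.

The central object is :class:`TabularDataset`, which stores the data matrix
``M`` in feature-major orientation (``d`` features x ``n`` samples) with one
integer class label in ``1..c`` per sample.  All downstream stages (feature
mapping, image synthesis, classification) consume this container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = [
    "TabularDataset",
    "SplitIndices",
    "read_table",
    "write_table",
    "split_dataset",
    "Norm2Normalizer",
    "fit_norm2",
    "apply_norm2",
]


@dataclass
class TabularDataset:
    """A feature matrix with class labels.

    Parameters
    ----------
    values : ndarray of shape (d, n)
        Feature-major data matrix: row ``i`` holds feature ``i`` across all
        ``n`` samples.
    labels : ndarray of shape (n,), optional
        Integer class labels in ``1..c``.  ``None`` for unlabeled data.
    feature_names : list of str
        ``d`` names; defaults to ``f1..fd``.
    sample_ids : list of str
        ``n`` identifiers; defaults to ``s1..sn``.
    metadata : dict
        Free-form provenance (generator parameters, label mapping, ...).
    """

    values: np.ndarray
    labels: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (features x samples) matrix")
        if np.isnan(self.values).any():
            raise ValueError("values contain NaN; apply an imputation policy at load time")
        d, n = self.values.shape
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError(f"labels shape {self.labels.shape} != ({n},)")
            if n and self.labels.min() < 1:
                raise ValueError("labels must be integers in 1..c")
        if not self.feature_names:
            self.feature_names = [f"f{i + 1}" for i in range(d)]
        if not self.sample_ids:
            self.sample_ids = [f"s{j + 1}" for j in range(n)]
        if len(self.feature_names) != d:
            raise ValueError("feature_names length must equal number of features")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must equal number of samples")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        if self.labels is None:
            return np.array([], dtype=int)
        return np.unique(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def sample(self, j: int) -> np.ndarray:
        """Column vector ``x_j`` of the ``j``-th sample."""
        return self.values[:, j]

    def subset(self, indices: np.ndarray) -> "TabularDataset":
        """New dataset restricted to the given sample indices (order kept)."""
        indices = np.asarray(indices, dtype=int)
        return TabularDataset(
            values=self.values[:, indices].copy(),
            labels=None if self.labels is None else self.labels[indices].copy(),
            feature_names=list(self.feature_names),
            sample_ids=[self.sample_ids[j] for j in indices],
            metadata=dict(self.metadata),
        )

    def to_frame(self) -> pd.DataFrame:
        """Samples-as-rows DataFrame with a trailing ``label`` column."""
        df = pd.DataFrame(self.values.T, columns=self.feature_names, index=self.sample_ids)
        if self.labels is not None:
            df["label"] = self.labels
        return df


@dataclass
class SplitIndices:
    """Disjoint train/validation/test sample indices."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=int)
        self.validation = np.asarray(self.validation, dtype=int)
        self.test = np.asarray(self.test, dtype=int)
        parts = [self.train, self.validation, self.test]
        total = np.concatenate(parts)
        if len(np.unique(total)) != len(total):
            raise ValueError("split parts are not disjoint")

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.train), len(self.validation), len(self.test)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "train": self.train.tolist(),
            "validation": self.validation.tolist(),
            "test": self.test.tolist(),
            "seed": self.seed,
            "stratified": self.stratified,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitIndices":
        payload = json.loads(Path(path).read_text())
        return cls(
            train=payload["train"],
            validation=payload["validation"],
            test=payload["test"],
            seed=payload["seed"],
            stratified=payload["stratified"],
        )


def read_table(
    path: str | Path,
    label_column: str = "label",
    delimiter: str | None = None,
    missing: str = "error",
) -> TabularDataset:
    """Read a delimited text file (samples as rows) into a :class:`TabularDataset`.

    Labels may be arbitrary (strings, ints); they are encoded to ``1..c`` in
    stable sorted order and the mapping is stored in ``metadata['label_map']``.

    Parameters
    ----------
    missing : {'error', 'median'}
        ``'error'`` raises on any missing feature cell, naming its location;
        ``'median'`` imputes per-feature medians (computed over this file).
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=delimiter)
    if label_column not in df.columns:
        raise KeyError(f"label column {label_column!r} not found in {path.name} "
                       f"(columns: {list(df.columns)[:8]}...)")
    raw_labels = df[label_column]
    feat = df.drop(columns=[label_column])
    try:
        feat = feat.astype(float)
    except (ValueError, TypeError) as exc:
        # locate the first offending cell for the error message
        for col in feat.columns:
            coerced = pd.to_numeric(feat[col], errors="coerce")
            bad = coerced.isna() & feat[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"non-numeric value {feat[col].iloc[row]!r} at row {row}, "
                    f"column {col!r}"
                ) from exc
        raise
    if feat.isna().any().any():
        if missing == "error":
            col = feat.columns[feat.isna().any().to_numpy()][0]
            row = int(np.flatnonzero(feat[col].isna().to_numpy())[0])
            raise ValueError(f"missing value at row {row}, column {col!r} "
                             "(policy='error'; use missing='median' to impute)")
        elif missing == "median":
            feat = feat.fillna(feat.median())
        else:
            raise ValueError(f"unknown missing-value policy {missing!r}")
    uniq = sorted(raw_labels.unique(), key=str)
    label_map = {lab: i + 1 for i, lab in enumerate(uniq)}
    labels = raw_labels.map(label_map).to_numpy()
    return TabularDataset(
        values=feat.to_numpy().T,
        labels=labels,
        feature_names=list(feat.columns),
        sample_ids=[str(i) for i in df.index],
        metadata={"source": str(path), "label_map": {str(k): v for k, v in label_map.items()},
                  "missing_policy": missing},
    )


def write_table(ds: TabularDataset, path: str | Path, delimiter: str = ",") -> None:
    """Write samples-as-rows delimited text with a trailing ``label`` column."""
    ds.to_frame().to_csv(path, sep=delimiter, index=False)


def split_dataset(
    ds: TabularDataset,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    stratified: bool = True,
) -> SplitIndices:
    """Deterministic (optionally stratified) train/validation/test split.

    The default 80:10:10 split of 7400 samples yields exactly 5920/740/740.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = ds.n_samples
    labels = ds.labels if stratified else None
    if stratified:
        if labels is None:
            raise ValueError("stratified split requires labels")
        counts = np.bincount(labels)
        if (counts[counts > 0] < 3).any():
            raise ValueError("every class needs >= 3 samples for a stratified 3-way split")
    idx = np.arange(n)
    train, rest = train_test_split(
        idx, train_size=fractions[0], random_state=seed,
        stratify=labels, shuffle=True,
    )
    rest_labels = labels[rest] if stratified else None
    if rest_labels is not None and np.bincount(rest_labels)[1:].min() < 2:
        rest_labels = None  # too few held-out samples per class to stratify further
    val_frac = fractions[1] / (fractions[1] + fractions[2])
    val, test = train_test_split(
        rest, train_size=val_frac, random_state=seed + 1,
        stratify=rest_labels, shuffle=True,
    )
    return SplitIndices(train=np.sort(train), validation=np.sort(val),
                        test=np.sort(test), seed=seed, stratified=stratified)


class Norm2Normalizer:
    """Per-feature rescaling of values into ``[0, 1]`` from training statistics.

    The default variant is per-feature min-max on the training partition with
    out-of-range test values clipped into ``[0, 1]``.  The ``'l2_minmax'``
    variant first divides each feature by its training L2 norm and then
    applies the same min-max; because min-max is invariant to positive
    scaling, both variants coincide on non-degenerate features (see the
    methods note).  Constant features map to 0.
    """

    def __init__(self, variant: str = "minmax") -> None:
        if variant not in {"minmax", "l2_minmax"}:
            raise ValueError(f"unknown variant {variant!r}")
        self.variant = variant
        self.mins_: np.ndarray | None = None
        self.maxs_: np.ndarray | None = None
        self.norms_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.mins_ is not None

    def fit(self, train: TabularDataset) -> "Norm2Normalizer":
        values = train.values
        if self.variant == "l2_minmax":
            norms = np.linalg.norm(values, axis=1)
            norms[norms == 0] = 1.0
            self.norms_ = norms
            values = values / norms[:, None]
        self.mins_ = values.min(axis=1)
        self.maxs_ = values.max(axis=1)
        return self

    def transform(self, ds: TabularDataset) -> TabularDataset:
        if not self.fitted:
            raise RuntimeError("Norm2Normalizer.transform called before fit")
        values = ds.values
        if values.shape[0] != len(self.mins_):
            raise ValueError("feature count differs from the fitted normalizer")
        if self.variant == "l2_minmax":
            values = values / self.norms_[:, None]
        span = self.maxs_ - self.mins_
        out = np.zeros_like(values)
        nz = span > 0
        out[nz] = (values[nz] - self.mins_[nz, None]) / span[nz, None]
        np.clip(out, 0.0, 1.0, out=out)
        return TabularDataset(
            values=out, labels=ds.labels, feature_names=list(ds.feature_names),
            sample_ids=list(ds.sample_ids), metadata=dict(ds.metadata),
        )

    def transform_vector(self, x: np.ndarray) -> np.ndarray:
        """Normalize a single raw sample vector of length ``d``."""
        if not self.fitted:
            raise RuntimeError("Norm2Normalizer.transform_vector called before fit")
        x = np.asarray(x, dtype=float)
        if self.variant == "l2_minmax":
            x = x / self.norms_
        span = self.maxs_ - self.mins_
        out = np.zeros_like(x)
        nz = span > 0
        out[nz] = (x[nz] - self.mins_[nz]) / span[nz]
        return np.clip(out, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "mins": self.mins_.tolist(),
            "maxs": self.maxs_.tolist(),
            "norms": None if self.norms_ is None else self.norms_.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Norm2Normalizer":
        obj = cls(variant=payload["variant"])
        obj.mins_ = np.asarray(payload["mins"], dtype=float)
        obj.maxs_ = np.asarray(payload["maxs"], dtype=float)
        if payload.get("norms") is not None:
            obj.norms_ = np.asarray(payload["norms"], dtype=float)
        return obj


def fit_norm2(train: TabularDataset, variant: str = "minmax") -> Norm2Normalizer:
    """Fit the normalizer on the training partition only."""
    return Norm2Normalizer(variant=variant).fit(train)


def apply_norm2(normalizer: Norm2Normalizer, ds: TabularDataset) -> TabularDataset:
    """Apply a fitted normalizer; raises if :func:`fit_norm2` was not called."""
    return normalizer.transform(ds)
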