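"""Baseline classifiers and the ringnorm benchmark experiment runner.

``run_baseline`` implements the shared tuning protocol: a small documented
hyperparameter grid is scored on the validation partition, the best point is
refit on the training partition and scored exactly once on the test
partition.  ``run_ringnorm_benchmark`` reproduces the full comparison on
freshly generated ringnorm data: four tabular baselines, single-
representation DeepInsight, and the three-representation soft-voting
ensemble, averaged over seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .classifier import TrainConfig
from .data import SplitIndices, TabularDataset, split_dataset
from .mapping import RepresentationSpec
from .pipeline import MRepPipeline, default_recipe
from .synthetic import GeneratorConfig, generate_ringnorm

__all__ = ["BaselineResult", "ExperimentReport", "run_baseline",
           "run_ringnorm_benchmark", "BASELINE_GRIDS"]

# Documented default grids; tuned on the validation partition only.
BASELINE_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {"n_estimators": [200], "max_features": ["sqrt", None]},
    "logreg_l2": {"C": [0.01, 0.1, 1.0, 10.0]},
    "gbt_levelwise": {"max_depth": [3, 6], "n_estimators": [300]},
    "gbt_leafwise": {"num_leaves": [31, 63], "n_estimators": [300]},
}


@dataclass
class BaselineResult:
    method: str
    accuracy: float  # test accuracy, percent
    best_params: dict
    val_accuracy: float
    seed: int
    audit: list[tuple[str, str]] = field(default_factory=list)


def _make_estimator(method: str, params: dict, seed: int):
    if method == "random_forest":
        from sklearn.ensemble import RandomForestClassifier
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if method == "logreg_l2":
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        # LogisticRegression penalizes with L2 by default
        return make_pipeline(StandardScaler(),
                             LogisticRegression(max_iter=2000, **params))
    if method == "gbt_levelwise":
        from xgboost import XGBClassifier
        return XGBClassifier(learning_rate=0.1, tree_method="hist",
                             random_state=seed, n_jobs=1, verbosity=0,
                             eval_metric="logloss", **params)
    if method == "gbt_leafwise":
        from lightgbm import LGBMClassifier
        return LGBMClassifier(learning_rate=0.1, random_state=seed, n_jobs=1,
                              verbose=-1, **params)
    raise ValueError(f"unknown baseline method {method!r}")


def run_baseline(
    ds: TabularDataset,
    split: SplitIndices,
    method: str,
    grid: dict[str, list] | None = None,
    seed: int = 0,
) -> BaselineResult:
    """Tune on validation, refit on train, score once on test (percent)."""
    if method not in BASELINE_GRIDS:
        raise ValueError(f"unknown baseline method {method!r}; "
                         f"choose from {sorted(BASELINE_GRIDS)}")
    grid = grid or BASELINE_GRIDS[method]
    X = ds.values.T
    y = ds.labels - 1  # estimators expect 0-based classes
    audit: list[tuple[str, str]] = []
    keys = sorted(grid)
    best_val, best_params = -np.inf, None
    import warnings
    best_est = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        for combo in product(*(grid[k] for k in keys)):
            params = dict(zip(keys, combo))
            est = _make_estimator(method, params, seed)
            est.fit(X[split.train], y[split.train])
            audit.append(("fit", "train"))
            val_acc = float(est.score(X[split.validation], y[split.validation]))
            audit.append(("score", "validation"))
            if val_acc > best_val:
                best_val, best_params, best_est = val_acc, params, est
        # the winning estimator was fitted on the training partition only,
        # so it is scored on test as-is
        test_acc = 100.0 * float(best_est.score(X[split.test], y[split.test]))
        audit.append(("score", "test"))
    return BaselineResult(method=method, accuracy=test_acc, best_params=best_params,
                          val_accuracy=100.0 * best_val, seed=seed, audit=audit)


@dataclass
class ExperimentReport:
    """Per-method, per-seed test accuracies plus a mean summary."""

    rows: list[dict]
    split_sizes: tuple[int, int, int]
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for row in self.rows:
            if not (0.0 <= row["accuracy"] <= 100.0):
                raise ValueError(f"accuracy out of range: {row}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def summary(self) -> pd.DataFrame:
        df = self.to_frame()
        return df.groupby("method", sort=False)["accuracy"].agg(["mean", "std", "count"])

    def to_markdown(self) -> str:
        out = self.summary().round(2)
        lines = ["| Method | Mean accuracy (%) | SD | Seeds |",
                 "|---|---|---|---|"]
        for method, row in out.iterrows():
            sd = "-" if np.isnan(row["std"]) else f"{row['std']:.2f}"
            lines.append(f"| {method} | {row['mean']:.2f} | {sd} | {int(row['count'])} |")
        return "\n".join(lines)


def run_ringnorm_benchmark(
    seeds: list[int],
    n_samples: int = 7400,
    n_features: int = 20,
    pixels: int = 24,
    train_config: TrainConfig | None = None,
    include_cnn: bool = True,
    methods: list[str] | None = None,
) -> ExperimentReport:
    """Full accuracy comparison on freshly generated ringnorm data.

    For each seed: generate the two-Gaussian dataset, split 80:10:10, run
    every baseline with validation tuning, then (optionally) train the
    image-ensemble classifier twice — once with a single t-SNE
    representation (the original single-map method) and once with the
    three-representation recipe — and score the held-out test set.
    """
    methods = methods if methods is not None else sorted(BASELINE_GRIDS)
    rows: list[dict] = []
    split_sizes = None
    for seed in seeds:
        cfg = GeneratorConfig(n_samples=n_samples, n_features=n_features,
                              seed=seed, family="ringnorm")
        ds = generate_ringnorm(cfg)
        split = split_dataset(ds, seed=seed)
        split_sizes = split.sizes
        for method in methods:
            res = run_baseline(ds, split, method, seed=seed)
            rows.append({"method": method, "seed": seed, "accuracy": res.accuracy,
                         "best_params": res.best_params})
        if include_cnn:
            tc = train_config or TrainConfig(seed=seed)
            single = [RepresentationSpec(technique="tsne", metric="euclidean", seed=seed)]
            for name, specs in [("deepinsight", single),
                                ("mrep_deepinsight", default_recipe(seed))]:
                pipe = MRepPipeline(specs, grid=(pixels, pixels), train_config=tc)
                pipe.fit(ds, split)
                _, acc = pipe.predict(ds.subset(split.test))
                rows.append({"method": name, "seed": seed, "accuracy": acc,
                             "best_params": None})
    return ExperimentReport(
        rows=rows, split_sizes=split_sizes,
        config={"n_samples": n_samples, "n_features": n_features,
                "pixels": pixels, "seeds": list(seeds)},
    )
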