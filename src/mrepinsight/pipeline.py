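"""End-to-end orchestration: normalize, map, render, train, soft-vote.

:class:`MRepPipeline` wires the stages together for the common case: fit on
a raw labeled dataset with a train/validation split, then classify raw test
samples.  All embeddings and the normalizer are fitted on the training
partition only; test samples reuse the frozen pixel maps.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .classifier import TrainConfig, TrainedModel, train
from .data import Norm2Normalizer, SplitIndices, TabularDataset
from .ensemble import Prediction, predict_batch
from .images import build_stacks
from .mapping import PixelMap, RepresentationSpec, compute_pixel_map
from .network import SmallCNN

__all__ = ["MRepPipeline", "default_recipe", "save_model", "load_model"]


def default_recipe(seed: int = 0, blur_sigma: float = 1.0) -> list[RepresentationSpec]:
    """The three-representation recipe used for the ringnorm experiments.

    t-SNE with hamming distances (features binarized at their medians),
    t-SNE with euclidean distances enhanced by Gaussian blurring, and UMAP.
    Each representation gets its own derived seed.
    """
    return [
        RepresentationSpec(technique="tsne", metric="hamming", seed=seed),
        RepresentationSpec(technique="tsne", metric="euclidean", filter="blur",
                           params={"sigma": blur_sigma}, seed=seed + 1),
        RepresentationSpec(technique="umap", seed=seed + 2),
    ]


class MRepPipeline:
    """Fit the full multi-representation image classifier on raw tabular data."""

    def __init__(
        self,
        specs: list[RepresentationSpec],
        grid: tuple[int, int] = (50, 50),
        train_config: TrainConfig | None = None,
        collision: str = "mean",
        norm_variant: str = "minmax",
    ) -> None:
        if not specs:
            raise ValueError("need at least one representation spec")
        self.specs = list(specs)
        self.grid = tuple(grid)
        self.train_config = train_config or TrainConfig()
        self.collision = collision
        self.norm_variant = norm_variant
        self.model: TrainedModel | None = None

    def fit(self, ds: TabularDataset, split: SplitIndices) -> "MRepPipeline":
        if ds.labels is None:
            raise ValueError("fit requires labels")
        train_ds = ds.subset(split.train)
        val_ds = ds.subset(split.validation)
        normalizer = Norm2Normalizer(variant=self.norm_variant).fit(train_ds)
        train_norm = normalizer.transform(train_ds)
        val_norm = normalizer.transform(val_ds)
        p, q = self.grid
        maps = [compute_pixel_map(train_norm, spec, p=p, q=q) for spec in self.specs]
        train_stacks = build_stacks(train_norm, maps, collision=self.collision)
        val_stacks = build_stacks(val_norm, maps, collision=self.collision)
        model = train(train_stacks, train_norm.labels, self.train_config,
                      val_stacks, val_norm.labels)
        model.normalizer = normalizer
        model.collision = self.collision
        self.model = model
        return self

    def predict(self, ds: TabularDataset) -> tuple[list[Prediction], float | None]:
        if self.model is None:
            raise RuntimeError("pipeline is not fitted")
        return predict_batch(ds, self.model)


def save_model(model: TrainedModel, out_dir: str | Path) -> None:
    """Persist a trained model: JSON manifest + pixel maps + weight arrays."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = model.config
    manifest = {
        "classes": model.classes.tolist(),
        "grid_shape": list(model.grid_shape),
        "collision": model.collision,
        "history": model.history,
        "config": None if cfg is None else {
            "backbone": cfg.backbone, "learning_rate": cfg.learning_rate,
            "weight_decay": cfg.weight_decay, "momentum": cfg.momentum,
            "epochs": cfg.epochs, "batch_size": cfg.batch_size, "seed": cfg.seed,
            "pretrained": cfg.pretrained, "channels": list(cfg.channels),
            "hidden": cfg.hidden,
        },
        "normalizer": None if model.normalizer is None else model.normalizer.to_dict(),
        "pixel_maps": [f"pixelmap_{r}.json" for r in range(model.n_representations)],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for r, pm in enumerate(model.pixel_maps):
        pm.to_json(out / f"pixelmap_{r}.json")
    arrays = {}
    for i, st in enumerate(model.network.get_state()):
        arrays[f"W{i}"] = st["W"]
        arrays[f"b{i}"] = st["b"]
    np.savez(out / "weights.npz", **arrays)


def load_model(model_dir: str | Path) -> TrainedModel:
    out = Path(model_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    cfg = manifest["config"]
    config = None if cfg is None else TrainConfig(
        backbone=cfg["backbone"], learning_rate=cfg["learning_rate"],
        weight_decay=cfg["weight_decay"], momentum=cfg["momentum"],
        epochs=cfg["epochs"], batch_size=cfg["batch_size"], seed=cfg["seed"],
        pretrained=cfg["pretrained"], channels=tuple(cfg["channels"]),
        hidden=cfg["hidden"],
    )
    pixel_maps = [PixelMap.from_json(out / name) for name in manifest["pixel_maps"]]
    classes = np.asarray(manifest["classes"], dtype=int)
    grid = tuple(manifest["grid_shape"])
    net = SmallCNN(grid, len(classes),
                   channels=config.channels if config else (8, 16, 32),
                   hidden=config.hidden if config else 64,
                   seed=config.seed if config else 0)
    with np.load(out / "weights.npz") as data:
        n_layers = sum(1 for k in data.files if k.startswith("W"))
        net.set_state([{"W": data[f"W{i}"], "b": data[f"b{i}"]} for i in range(n_layers)])
    normalizer = None
    if manifest["normalizer"] is not None:
        normalizer = Norm2Normalizer.from_dict(manifest["normalizer"])
    return TrainedModel(
        network=net, classes=classes, grid_shape=grid, pixel_maps=pixel_maps,
        history=manifest["history"], config=config, normalizer=normalizer,
        collision=manifest["collision"],
    )
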