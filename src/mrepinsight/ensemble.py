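"""Soft-voting inference over the m representations of a sample.

A test sample is pushed through each frozen pixel map (no re-fitting of
embeddings at test time), yielding m images; the trained network scores each
image, the per-representation probability rows are averaged without weights,
and the class with the highest average probability wins (lowest index on an
exact tie).  With m = 1 this reduces exactly to single-representation
DeepInsight classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import TrainedModel
from .data import TabularDataset
from .images import apply_filter, render_sample

__all__ = ["Prediction", "transform_test_sample", "average_probabilities",
           "classify", "predict_batch"]


@dataclass
class Prediction:
    """Per-representation probability rows, their average, and the label."""

    sample_id: str
    per_representation: np.ndarray  # (m, c)
    averaged: np.ndarray  # (c,)
    label: int  # original class label (from model.classes)


def transform_test_sample(x_t: np.ndarray, model: TrainedModel) -> list[np.ndarray]:
    """Render a normalized sample through every stored pixel map.

    Returns the m images ``Ts = {R_1, ..., R_m}``, each ``p x q`` with the
    representation's enhancement filter applied.
    """
    x_t = np.asarray(x_t, dtype=float)
    d = model.pixel_maps[0].n_features
    if x_t.shape != (d,):
        raise ValueError(f"sample has {x_t.shape} values; model was trained on d={d}")
    images = []
    for pm in model.pixel_maps:
        img = render_sample(x_t, pm, collision=model.collision)
        images.append(apply_filter(img, pm))
    return images


def average_probabilities(rows: np.ndarray) -> np.ndarray:
    """Unweighted arithmetic mean of the m probability rows."""
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2:
        raise ValueError("expected an (m, c) array of probability rows")
    sums = rows.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("each probability row must sum to 1")
    return rows.mean(axis=0)


def classify(rho_avg: np.ndarray) -> int:
    """Zero-based index of the maximum average probability (ties: lowest index)."""
    rho_avg = np.asarray(rho_avg, dtype=float)
    if rho_avg.size == 0:
        raise ValueError("empty probability vector")
    return int(np.argmax(rho_avg))


def predict_sample(x_t: np.ndarray, model: TrainedModel,
                   sample_id: str = "") -> Prediction:
    """Full soft-voting pipeline for one normalized sample."""
    images = transform_test_sample(x_t, model)
    rows = model.network.predict_proba(np.stack(images))
    rho_avg = average_probabilities(rows)
    omega = classify(rho_avg)
    return Prediction(sample_id=sample_id, per_representation=rows,
                      averaged=rho_avg, label=int(model.classes[omega]))


def predict_batch(ds_test: TabularDataset, model: TrainedModel,
                  normalized: bool = False) -> tuple[list[Prediction], float | None]:
    """Predictions for every sample; accuracy in percent when labels exist.

    ``ds_test`` is raw by default and is normalized with the training
    normalizer carried by the model; pass ``normalized=True`` if the values
    are already in [0, 1].
    """
    if ds_test.n_samples == 0:
        raise ValueError("empty test set")
    if not normalized:
        if model.normalizer is None:
            raise ValueError("model carries no normalizer; pass normalized data")
        ds_test = model.normalizer.transform(ds_test)
    predictions = [
        predict_sample(ds_test.values[:, j], model, sample_id=ds_test.sample_ids[j])
        for j in range(ds_test.n_samples)
    ]
    accuracy = None
    if ds_test.labels is not None:
        predicted = np.array([pr.label for pr in predictions])
        accuracy = 100.0 * float((predicted == ds_test.labels).mean())
    return predictions, accuracy


def predictions_to_frame(predictions: list[Prediction],
                         classes: np.ndarray) -> pd.DataFrame:
    """Tabulate predictions: sample id, averaged per-class probabilities, label."""
    rows = []
    for pr in predictions:
        row = {"sample_id": pr.sample_id}
        row.update({f"p_class{c}": pr.averaged[i] for i, c in enumerate(classes)})
        row["predicted_label"] = pr.label
        rows.append(row)
    return pd.DataFrame(rows)
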