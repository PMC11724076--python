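"""Train one classifier on the pooled n*m images of all representations.

Every image inherits the class label of its source sample, so a sample
contributes ``m`` labeled images — the pooled set acts like a structured
augmentation of the training data.  The epoch whose weights minimize the
validation loss is kept (checkpoint-best).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .images import ImageStack
from .mapping import PixelMap
from .network import SmallCNN

__all__ = ["TrainConfig", "TrainedModel", "train", "predict_probabilities"]

_BACKBONES = {"small_cnn", "resnet50", "efficientnet_b6"}


@dataclass
class TrainConfig:
    """Hyperparameters (the paper's theta) for model estimation.

    The printed lr=0.001 / weight_decay=0.0001 / momentum=0.9 belong to the
    pretrained large-backbone setup; the from-scratch small CNN defaults to
    a larger step size (see the methods note).  ``weight_decay`` and
    ``momentum`` keep the printed values.
    """

    backbone: str = "small_cnn"
    learning_rate: float = 0.01
    weight_decay: float = 1e-4
    momentum: float = 0.9
    epochs: int = 15
    batch_size: int = 128
    seed: int = 0
    pretrained: bool = False
    channels: tuple[int, ...] = (8, 16, 32)
    hidden: int = 64

    def __post_init__(self) -> None:
        if self.backbone not in _BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning rate, epochs and batch size must be positive")
        if self.pretrained and self.backbone == "small_cnn":
            raise ValueError("pretrained weights exist only for the named large backbones")


@dataclass
class TrainedModel:
    """A trained network plus everything needed to classify raw samples."""

    network: SmallCNN
    classes: np.ndarray  # original labels, sorted; position = network output index
    grid_shape: tuple[int, int]
    pixel_maps: list[PixelMap]
    history: list[dict] = field(default_factory=list)
    config: TrainConfig | None = None
    normalizer: object | None = None  # Norm2Normalizer, set by the pipeline
    collision: str = "mean"

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def n_representations(self) -> int:
        return len(self.pixel_maps)


def _pool_stacks(stacks: list[ImageStack], labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate all representations' images; labels are tiled per stack."""
    n = stacks[0].n_images
    for st in stacks:
        if st.n_images != n:
            raise ValueError("all stacks must contain one image per sample")
    if len(labels) != n:
        raise ValueError(f"{len(labels)} labels for {n} samples")
    images = np.concatenate([st.images for st in stacks], axis=0)
    pooled_labels = np.tile(np.asarray(labels), len(stacks))
    return images, pooled_labels


def train(
    stacks: list[ImageStack],
    labels: np.ndarray,
    config: TrainConfig | None = None,
    val_stacks: list[ImageStack] | None = None,
    val_labels: np.ndarray | None = None,
) -> TrainedModel:
    """Fit the backbone on the pooled ``n*m`` training images.

    Validation loss is evaluated after every epoch on the pooled validation
    images and the best-epoch weights are restored at the end.  With no
    validation set the last-epoch weights are kept (with a warning).
    """
    config = config or TrainConfig()
    if config.backbone != "small_cnn":
        raise RuntimeError(
            f"backbone {config.backbone!r} requires a deep-learning framework with "
            "pretrained weights (e.g. torch); install one and register the backbone, "
            "or use the default 'small_cnn'"
        )
    if not stacks:
        raise ValueError("need at least one image stack")
    images, y_raw = _pool_stacks(stacks, labels)
    classes = np.unique(y_raw)
    if len(classes) < 2:
        raise ValueError("training set must contain at least two classes")
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.array([class_index[c] for c in y_raw])

    has_val = val_stacks is not None and val_labels is not None and len(val_labels) > 0
    if has_val:
        missing = set(np.unique(val_labels)) - set(classes.tolist())
        if missing:
            raise ValueError(f"validation classes {sorted(missing)} absent from training set")
        val_images, vy_raw = _pool_stacks(val_stacks, val_labels)
        vy = np.array([class_index[c] for c in vy_raw])
    else:
        warnings.warn("no validation set: keeping last-epoch weights", stacklevel=2)

    p, q = stacks[0].pixel_map.p, stacks[0].pixel_map.q
    net = SmallCNN((p, q), len(classes), channels=config.channels,
                   hidden=config.hidden, seed=config.seed)
    velocity = net.init_velocity()
    rng = np.random.default_rng(config.seed + 1)
    x = images[:, None]  # (N, 1, p, q)

    history: list[dict] = []
    best_state, best_val_loss = None, np.inf
    for epoch in range(config.epochs):
        order = rng.permutation(len(y))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            sel = order[start:start + config.batch_size]
            loss = net.loss_and_grads(x[sel], y[sel])
            net.sgd_step(config.learning_rate, config.momentum, config.weight_decay, velocity)
            epoch_loss += loss
            n_batches += 1
        record = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)}
        if has_val:
            probs = net.predict_proba(val_images)
            val_loss = float(-np.log(np.clip(probs[np.arange(len(vy)), vy], 1e-12, None)).mean())
            record["val_loss"] = val_loss
            record["val_accuracy"] = float((probs.argmax(axis=1) == vy).mean())
            if val_loss < best_val_loss:
                best_val_loss = val_loss
                best_state = net.clone_state()
        history.append(record)
    if best_state is not None:
        net.set_state(best_state)

    return TrainedModel(
        network=net, classes=classes, grid_shape=(p, q),
        pixel_maps=[st.pixel_map for st in stacks], history=history, config=config,
    )


def predict_probabilities(model: TrainedModel, image: np.ndarray) -> np.ndarray:
    """Per-class probabilities ``rho`` for one image (softmax contract)."""
    image = np.asarray(image, dtype=float)
    if image.shape != model.grid_shape:
        raise ValueError(f"image shape {image.shape} != model grid {model.grid_shape}")
    return model.network.predict_proba(image[None])[0]
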