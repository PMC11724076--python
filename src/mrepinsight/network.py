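"""A small convolutional network implemented in pure numpy.

This is the default desk-scale backbone: three conv(3x3)-ReLU-maxpool blocks
followed by a hidden dense layer and a softmax head (~100k parameters for
the default widths).  Convolutions use im2col views (``sliding_window_view``)
so the heavy lifting is BLAS matrix products; training is plain SGD with
momentum and L2 weight decay.  Everything is deterministic given the seed,
which large-framework backends cannot always promise.

The network consumes single-channel images of shape ``(B, 1, p, q)`` with
values in [0, 1] and produces class probabilities via a numerically stable
softmax.
"""

from __future__ import annotations

import copy
import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SmallCNN", "softmax"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class _Conv3x3:
    """Stride-1, pad-1 ('same') 3x3 convolution."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        scale = math.sqrt(2.0 / (c_in * 9))  # He initialization
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, 3, 3))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (B,C,H,W,3,3)
        out = np.tensordot(win, self.W, axes=([1, 4, 5], [1, 2, 3]))  # (B,H,W,O)
        out = out.transpose(0, 3, 1, 2) + self.b[None, :, None, None]
        if cache:
            self._win = win
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = np.tensordot(dout, self._win, axes=([0, 2, 3], [0, 2, 3]))
        self.db = dout.sum(axis=(0, 2, 3))
        dp = np.pad(dout, ((0, 0), (0, 0), (1, 1), (1, 1)))
        dwin = sliding_window_view(dp, (3, 3), axis=(2, 3))  # (B,O,H,W,3,3)
        Wf = self.W[:, :, ::-1, ::-1]
        dx = np.tensordot(dwin, Wf, axes=([1, 4, 5], [0, 2, 3]))  # (B,H,W,C)
        self._win = None
        return dx.transpose(0, 3, 1, 2)

    def params(self):
        return [("W", self), ("b", self)]


class _ReLU:
    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if cache:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx

    def params(self):
        return []


class _MaxPool2:
    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        B, C, H, W = x.shape
        Hp, Wp = H // 2, W // 2
        xc = x[:, :, : 2 * Hp, : 2 * Wp]
        blocks = xc.reshape(B, C, Hp, 2, Wp, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(B, C, Hp, Wp, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if cache:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        Hp, Wp = H // 2, W // 2
        flat = np.zeros((B, C, Hp, Wp, 4))
        np.put_along_axis(flat, self._idx[..., None], dout[..., None], axis=-1)
        blocks = flat.reshape(B, C, Hp, Wp, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros((B, C, H, W))
        dx[:, :, : 2 * Hp, : 2 * Wp] = blocks.reshape(B, C, 2 * Hp, 2 * Wp)
        self._idx = None
        return dx

    def params(self):
        return []


class _Flatten:
    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        if cache:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        scale = math.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        if cache:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        self._x = None
        return dout @ self.W.T


class SmallCNN:
    """Three conv-ReLU-pool blocks, one hidden dense layer, softmax head."""

    def __init__(self, input_shape: tuple[int, int], n_classes: int,
                 channels: tuple[int, ...] = (8, 16, 32), hidden: int = 64,
                 seed: int = 0) -> None:
        if n_classes < 2:
            raise ValueError("need at least two classes")
        p, q = input_shape
        rng = np.random.default_rng(seed)
        self.input_shape = (p, q)
        self.n_classes = n_classes
        self.layers: list = []
        c_in, hh, ww = 1, p, q
        for c_out in channels:
            if hh < 2 or ww < 2:
                break  # grid too small for another pooling stage
            self.layers += [_Conv3x3(c_in, c_out, rng), _ReLU(), _MaxPool2()]
            c_in, hh, ww = c_out, hh // 2, ww // 2
        self.layers.append(_Flatten())
        n_flat = c_in * hh * ww
        self.layers += [_Dense(n_flat, hidden, rng), _ReLU(), _Dense(hidden, n_classes, rng)]

    # --- parameter plumbing -------------------------------------------------
    def _param_layers(self):
        return [lay for lay in self.layers if isinstance(lay, (_Conv3x3, _Dense))]

    @property
    def n_parameters(self) -> int:
        return sum(lay.W.size + lay.b.size for lay in self._param_layers())

    def get_state(self) -> list[dict]:
        return [{"W": lay.W.copy(), "b": lay.b.copy()} for lay in self._param_layers()]

    def set_state(self, state: list[dict]) -> None:
        for lay, st in zip(self._param_layers(), state):
            lay.W = st["W"].copy()
            lay.b = st["b"].copy()

    # --- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        """Logits for a batch of images of shape (B, 1, p, q)."""
        out = x
        for lay in self.layers:
            out = lay.forward(out, cache)
        return out

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray) -> float:
        """Mean softmax cross-entropy; gradients stored on the layers."""
        logits = self.forward(x, cache=True)
        probs = softmax(logits)
        B = len(y)
        loss = -np.log(np.clip(probs[np.arange(B), y], 1e-12, None)).mean()
        dlogits = probs
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        dout = dlogits
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return float(loss)

    def predict_proba(self, images: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Class probabilities for (n, p, q) or (n, 1, p, q) images."""
        images = np.asarray(images, dtype=float)
        if images.ndim == 3:
            images = images[:, None]
        out = np.zeros((len(images), self.n_classes))
        for start in range(0, len(images), batch_size):
            chunk = images[start:start + batch_size]
            out[start:start + len(chunk)] = softmax(self.forward(chunk))
        return out

    # --- optimization -------------------------------------------------------
    def sgd_step(self, lr: float, momentum: float, weight_decay: float,
                 velocity: list[dict]) -> None:
        for lay, vel in zip(self._param_layers(), velocity):
            for name in ("W", "b"):
                g = getattr(lay, "d" + name)
                if name == "W" and weight_decay:
                    g = g + weight_decay * getattr(lay, name)
                vel[name] = momentum * vel[name] - lr * g
                setattr(lay, name, getattr(lay, name) + vel[name])

    def init_velocity(self) -> list[dict]:
        return [{"W": np.zeros_like(lay.W), "b": np.zeros_like(lay.b)}
                for lay in self._param_layers()]

    def clone_state(self) -> list[dict]:
        return copy.deepcopy(self.get_state())
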