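"""Render samples through pixel maps into image stacks, with enhancement filters.

A normalized sample vector ``x`` in ``[0,1]^d`` becomes a ``p x q`` image by
writing each feature value at its pixel ``[a_i, b_i]``; features that share a
pixel are aggregated (mean by default, max available).  Optional Gaussian
blurring or a Gabor filter bank is applied to the rendered image, never to
the embedding coordinates.  One :class:`ImageStack` holds the ``n`` images of
one representation; stacking over ``m`` representations yields the ``n*m``
training images the classifier consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .data import TabularDataset
from .mapping import PixelMap

__all__ = ["ImageStack", "render_sample", "apply_blur", "apply_gabor",
           "apply_filter", "build_stacks"]


@dataclass
class ImageStack:
    """The images ``E_r`` of one representation: shape ``(n, p, q)`` in [0, 1]."""

    rep_index: int
    images: np.ndarray
    pixel_map: PixelMap

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must have shape (n, p, q)")
        if self.images.shape[1:] != (self.pixel_map.p, self.pixel_map.q):
            raise ValueError("image shape does not match the pixel map grid")
        if self.images.size and (self.images.min() < -1e-9 or self.images.max() > 1 + 1e-9):
            raise ValueError("image values must lie in [0, 1]")

    @property
    def n_images(self) -> int:
        return self.images.shape[0]


def render_sample(x: np.ndarray, pixel_map: PixelMap, collision: str = "mean") -> np.ndarray:
    """Map one normalized sample vector onto the pixel grid.

    Background pixels are 0; each occupied pixel holds the mean (or max) of
    the values of all features assigned to it.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (pixel_map.n_features,):
        raise ValueError(f"sample length {x.shape} != number of mapped features "
                         f"({pixel_map.n_features},)")
    if collision not in {"mean", "max"}:
        raise ValueError(f"collision must be 'mean' or 'max', got {collision!r}")
    img = np.zeros((pixel_map.p, pixel_map.q))
    a, b = pixel_map.coords[:, 0], pixel_map.coords[:, 1]
    if collision == "mean":
        np.add.at(img, (a, b), x)
        counts = np.zeros_like(img)
        np.add.at(counts, (a, b), 1.0)
        occupied = counts > 0
        img[occupied] /= counts[occupied]
    else:
        np.maximum.at(img, (a, b), x)
    return img


def apply_blur(image: np.ndarray, sigma: float = 1.0, renormalize: bool = True) -> np.ndarray:
    """Gaussian blur with reflective borders.

    With ``renormalize`` the output is rescaled so its maximum equals the
    input maximum (keeping a [0,1] input in [0,1]); pass ``False`` to get the
    raw convolution, which conserves total mass.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    image = np.asarray(image, dtype=float)
    out = ndimage.gaussian_filter(image, sigma=sigma, mode="reflect", truncate=4.0)
    if renormalize:
        peak = out.max()
        if peak > 0:
            out = out * (image.max() / peak)
    return out


def default_gabor_bank(n_orientations: int = 4,
                       frequencies: tuple[float, ...] = (0.1, 0.25)) -> list[tuple[float, float]]:
    """(theta, frequency) pairs: ``n_orientations`` angles x given frequencies."""
    thetas = [np.pi * k / n_orientations for k in range(n_orientations)]
    return [(t, f) for t in thetas for f in frequencies]


def apply_gabor(image: np.ndarray, bank: list[tuple[float, float]] | None = None) -> np.ndarray:
    """Maximum Gabor response magnitude across a filter bank, rescaled to [0, 1].

    ``bank`` is a list of (orientation, spatial frequency) pairs; default
    4 orientations x 2 frequencies.
    """
    from skimage.filters import gabor
    if bank is None:
        bank = default_gabor_bank()
    if not bank:
        raise ValueError("Gabor bank must not be empty")
    image = np.asarray(image, dtype=float)
    best = np.zeros_like(image)
    for theta, frequency in bank:
        real, imag = gabor(image, frequency=frequency, theta=theta, mode="reflect")
        mag = np.hypot(real, imag)
        np.maximum(best, mag, out=best)
    peak = best.max()
    if peak > 0:
        best = best / peak
    return best


def apply_filter(image: np.ndarray, pixel_map: PixelMap) -> np.ndarray:
    """Apply the enhancement filter named in the map's representation spec."""
    spec = pixel_map.spec
    if spec.filter == "none":
        return image
    if spec.filter == "blur":
        return apply_blur(image, sigma=float(spec.params.get("sigma", 1.0)))
    if spec.filter == "gabor":
        bank = spec.params.get("gabor_bank")
        if bank is None:
            bank = default_gabor_bank(
                n_orientations=int(spec.params.get("n_orientations", 4)),
                frequencies=tuple(spec.params.get("frequencies", (0.1, 0.25))),
            )
        return apply_gabor(image, bank=bank)
    raise ValueError(f"unknown filter {spec.filter!r}")


def render_all(ds: TabularDataset, pixel_map: PixelMap, collision: str = "mean",
               filtered: bool = True) -> np.ndarray:
    """Render every sample of a (normalized) dataset through one map."""
    n = ds.n_samples
    images = np.zeros((n, pixel_map.p, pixel_map.q))
    for j in range(n):
        img = render_sample(ds.values[:, j], pixel_map, collision=collision)
        images[j] = apply_filter(img, pixel_map) if filtered else img
    return images


def build_stacks(ds: TabularDataset, maps: list[PixelMap],
                 collision: str = "mean") -> list[ImageStack]:
    """One :class:`ImageStack` per representation; ``n * m`` images in total.

    All maps must share the grid size so a single network consumes them.
    """
    if not maps:
        raise ValueError("need at least one pixel map")
    grids = {(pm.p, pm.q) for pm in maps}
    if len(grids) > 1:
        raise ValueError(f"all representations must share one grid size, got {sorted(grids)}")
    return [
        ImageStack(rep_index=r, images=render_all(ds, pm, collision=collision), pixel_map=pm)
        for r, pm in enumerate(maps)
    ]
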