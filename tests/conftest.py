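import numpy as np
import pytest

from mrepinsight import (GeneratorConfig, PixelMap, RepresentationSpec,
                         generate_blobs, generate_ringnorm, split_dataset)


@pytest.fixture(scope="session")
def blobs_ds():
    """Small, well-separated 3-class fixture for fast pipeline tests."""
    cfg = GeneratorConfig(n_samples=120, n_features=8,
                          class_fractions=(0.4, 0.3, 0.3), seed=3,
                          family="gaussian_blobs", params={"separation": 10.0})
    return generate_blobs(cfg)


@pytest.fixture(scope="session")
def blobs_split(blobs_ds):
    return split_dataset(blobs_ds, fractions=(0.6, 0.2, 0.2), seed=0)


@pytest.fixture(scope="session")
def small_ringnorm():
    cfg = GeneratorConfig(n_samples=600, n_features=20, seed=7, family="ringnorm")
    return generate_ringnorm(cfg)


@pytest.fixture
def toy_map():
    """Hand-set 5-feature map on a 4x4 grid (features 3 and 4 collide)."""
    coords = np.array([[0, 0], [1, 2], [3, 3], [2, 1], [2, 1]])
    return PixelMap(p=4, q=4, coords=coords, rotation_deg=0.0,
                    spec=RepresentationSpec(technique="pca"))
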