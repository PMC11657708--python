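import numpy as np
import pytest

from usplane.imgproc import GrayImage, LabeledDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    return GrayImage(rng.integers(0, 256, size=(32, 32), dtype=np.uint8))


def make_dataset(counts, rng, shape=(8, 8)):
    """Lightweight labeled dataset with the given per-class counts."""
    images, labels = [], []
    for label, count in enumerate(counts):
        for _ in range(count):
            images.append(GrayImage(rng.integers(0, 256, size=shape, dtype=np.uint8)))
            labels.append(label)
    return LabeledDataset(images, np.asarray(labels))


@pytest.fixture
def tiny_dataset(rng):
    return make_dataset((5, 4, 6), rng)
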