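import numpy as np
import pytest

from freqlens.synthdata import BandDatasetSpec, make_band_dataset, train_tiny_cnn


@pytest.fixture(scope="session")
def easy2_dataset():
    """Two well-separated frequency classes at desk scale."""
    spec = BandDatasetSpec(
        n_classes=2,
        images_per_class=120,
        size=(16, 16),
        class_bands=((0.1, 0.4), (0.6, 0.9)),
        template_components=3,
        noise_std=0.05,
        amplitude_slope=0.0,
        noise_exponent=0.0,
        seed=42,
    )
    return make_band_dataset(spec)


@pytest.fixture(scope="session")
def easy2_cnn(easy2_dataset):
    """Tiny CNN trained on the easy two-class dataset (first 160 images)."""
    ds = easy2_dataset
    train = ds._replace(images=ds.images[:160], labels=ds.labels[:160])
    return train_tiny_cnn(train, epochs=10, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
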