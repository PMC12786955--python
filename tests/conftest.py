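import numpy as np
import pytest

from condvae import pipeline, synthetic
from condvae.conditions import make_scheme
from condvae.model import ConditionCVAE, EncoderConfig, TrainConfig


@pytest.fixture(scope="session")
def small_spec():
    """Small S-like synthetic corpus specification (fast to render)."""
    return synthetic.GeneratorSpec(n_transformations=150, noise_rate=0.1, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    records = synthetic.generate_dataset(small_spec)
    train, test = synthetic.split_train_test(records, 0.15, seed=11)
    return train, test


@pytest.fixture(scope="session")
def small_features(small_dataset):
    train, test = small_dataset
    X, comp = pipeline.featurize([r.smiles for r in train])
    Y = np.stack([r.condition.as_array() for r in train])
    mask = np.array([r.tp_mask for r in train], dtype=bool)
    return X, Y, mask, comp


@pytest.fixture(scope="session")
def tiny_trained_model(small_spec, small_features):
    """A g-CVAE trained briefly on the small corpus — enough for contracts."""
    X, Y, mask, comp = small_features
    model = ConditionCVAE(
        small_spec.scheme, comp.dim,
        encoder=EncoderConfig(latent_dim=8, family="gaussian"),
        train=TrainConfig(epochs=5, seed=3))
    model.fit(X, Y, mask)
    return model


@pytest.fixture
def scheme_s():
    return make_scheme("S")


@pytest.fixture
def scheme_b():
    return make_scheme("B")
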