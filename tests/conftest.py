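import numpy as np
import pytest

from motcs.encoder import EncoderConfig
from motcs.model import MOTCSConfig
from motcs.synthetic import SyntheticSpec, make_worked_fixture, \
    preprocess_bundle, simulate_multiomics
from motcs.train import TrainConfig, run_cv


@pytest.fixture
def worked():
    """The deterministic 8-sample hand-checkable bundle."""
    return make_worked_fixture()


MICRO_SPEC = SyntheticSpec(n_samples=100, n_features=40, n_informative=10,
                           n_informative_driver=4, n_decoy_drivers=4,
                           seed=5)
MICRO_ENCODER = EncoderConfig(embed_dim=8, num_heads=2, num_layers=1,
                              dropout_rate=0.1)
MICRO_TRAIN = TrainConfig(learning_rate=1e-2, batch_size=128, max_epochs=25,
                          early_stop_patience=25, seed=3, val_fraction=0.0)


def micro_model_config(num_classes: int) -> MOTCSConfig:
    return MOTCSConfig(views=["mRNA", "miRNA", "methylation"],
                       num_classes=num_classes,
                       encoder_driver=MICRO_ENCODER,
                       encoder_nondriver=MICRO_ENCODER, mlp_hidden=16)


@pytest.fixture(scope="session")
def micro_data():
    """A small synthetic bundle with its preprocessed views."""
    bundle = simulate_multiomics(MICRO_SPEC)
    return bundle, preprocess_bundle(bundle)


@pytest.fixture(scope="session")
def micro_cv(micro_data):
    """One quick 3-fold CV run on the micro dataset, shared by tests that
    need fitted models (importance, persistence, reproducibility...)."""
    bundle, views = micro_data
    cfg = micro_model_config(len(bundle.labels.class_names))
    cv = run_cv(views, bundle.labels, bundle.catalog, cfg, MICRO_TRAIN,
                n_folds=3)
    return bundle, views, cfg, cv
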