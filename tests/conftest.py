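import numpy as np
import pytest

from contexseg.model import ModelConfig, TrainConfig, train_model
from contexseg.modifications import ModificationSetting
from contexseg.phantom import Protocol, make_anatomy, simulate_image


@pytest.fixture(scope="session")
def toy_phantom():
    """One noiseless 32x32 phantom: the overfit-one-example target."""
    anatomy = make_anatomy(seed=7, size=(32, 32), variability=0.3)
    return simulate_image(
        anatomy, Protocol(tr_ms=500, te_ms=25), noise_sigma=0.0, seed=0
    )


@pytest.fixture(scope="session")
def toy_model(toy_phantom):
    """A small net overfit on the single noiseless phantom.

    Shared by the training-sanity, prediction and saliency tests;
    training one example to high Dice is the standard overfit oracle.
    """
    cfg = ModelConfig(input_size=(32, 32), depth=2, base_channels=8,
                      dropout_rate=0.0)
    tcfg = TrainConfig(epochs=150, learning_rate=5e-3, batch_size=1, seed=0)
    return train_model([toy_phantom], [toy_phantom],
                       ModificationSetting.none(), cfg, tcfg)
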