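import warnings

import numpy as np
import pytest

from knotfold import equilibrium, synthdata


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    """Fits on deliberately degenerate synthetic data warn; keep logs clean."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def three_state_model():
    """Reference three-state model: first transition at 2 M, second at ~2.9 M."""
    return equilibrium.ThreeStateModel(3.0, 1.5, 8.95, 3.06)


@pytest.fixture
def denaturation_series(three_state_model):
    return synthdata.gen_denaturation_series(three_state_model, noise_sd=0.01, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
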