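import numpy as np
import pytest

from dropfrap import ModelParams


@pytest.fixture(scope="session")
def green_params() -> ModelParams:
    """Condensate-like reference parameter set used across tests.

    D_in = 0.01 um^2/s (the fixed in-silico inside diffusivity),
    D_out = 0.1 um^2/s, P = 150, R = 5 um, thin interface ell = R/100.
    """
    return ModelParams.from_p(D_in=0.01, D_out=0.1, R=5.0, P=150.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
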