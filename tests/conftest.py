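import numpy as np
import pytest

from bxiime import Params

# a spread of shapes: heavy-tailed, sub-model boundaries, light-tailed
PARAM_GRID = [
    Params(0.5, 0.5, 1.0),
    Params(0.25, 3.0, 3.0),
    Params(5.0, 2.0, 0.5),
    Params(1.0, 1.0, 1.0),
    Params(1.0, 4.0, 2.0),
    Params(2.0, 1.0, 0.7),
]


@pytest.fixture
def rng():
    return np.random.default_rng(20210222)


@pytest.fixture(params=PARAM_GRID, ids=lambda p: f"a{p.alpha}-b{p.beta}-l{p.lam}")
def params(request) -> Params:
    return request.param
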