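import numpy as np
import pytest

from gazemix import ModelParams, SaliencyMap, synthetic_saliency


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_map():
    """A 24x24 three-mode synthetic saliency map."""
    return synthetic_saliency((24, 24), 3, seed=7)


@pytest.fixture
def uniform_map():
    return SaliencyMap(np.full((20, 20), 1.0 / 400.0))


@pytest.fixture
def full_params():
    return ModelParams(eps_x=4.0, eps_y=4.0, xi_x=80.0, xi_y=80.0, b=2.0, s_o=1.0)


def brute_force_gauss(shape, center, var_x, var_y):
    """Independent direct evaluation of the raw bivariate diagonal Gaussian
    density at every pixel center (loop-based, no shortcuts)."""
    h, w = shape
    out = np.empty((h, w))
    cx, cy = center
    const = 1.0 / (2.0 * np.pi * np.sqrt(var_x * var_y))
    for y in range(h):
        for x in range(w):
            out[y, x] = const * np.exp(
                -((x - cx) ** 2) / (2 * var_x) - ((y - cy) ** 2) / (2 * var_y)
            )
    return out
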