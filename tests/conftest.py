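import numpy as np
import pytest

from ttquant.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default (noisy, zero-dropout) phantom."""
    return generate_phantom(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(PhantomSpec(seed=3, noise_amplitude=0.0))


@pytest.fixture(scope="session")
def transverse_only_phantom():
    """Noisy phantom containing only transverse tubule lines."""
    return generate_phantom(PhantomSpec(seed=5, p_drop_l=1.0))


def random_blob(rng: np.random.Generator, shape=(48, 48), n_seeds=4, iters=6):
    """Random connected-ish blob mask for property tests."""
    from scipy import ndimage

    mask = np.zeros(shape, dtype=bool)
    ys = rng.integers(8, shape[0] - 8, size=n_seeds)
    xs = rng.integers(8, shape[1] - 8, size=n_seeds)
    mask[ys, xs] = True
    mask = ndimage.binary_dilation(mask, iterations=iters)
    return mask
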