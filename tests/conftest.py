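import numpy as np
import pytest

import ehquant as eq


@pytest.fixture(scope="session")
def noiseless_spec():
    return eq.PhantomSpec(noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def noiseless_mr(noiseless_spec):
    return eq.render_mr_phantom(noiseless_spec)


@pytest.fixture(scope="session")
def noiseless_mi2(noiseless_mr):
    mrc, ppi, pei, labels = noiseless_mr
    return eq.compose_mi2(eq.compose_hydrops(ppi, pei), mrc), labels


@pytest.fixture(scope="session")
def vestibule_section(noiseless_spec):
    return eq.render_histo_section(noiseless_spec, "vestibule")


@pytest.fixture(scope="session")
def cochlea_section(noiseless_spec):
    return eq.render_histo_section(noiseless_spec, "cochlea")


def shoelace_area(poly: np.ndarray) -> float:
    """Independent polygon-area oracle (shoelace formula)."""
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
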