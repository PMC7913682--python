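import numpy as np
import pytest

from splicedex import simulate


@pytest.fixture(scope="session")
def panel36():
    """The bundled synthetic 36-event panel (deterministic)."""
    return simulate.synthetic_panel()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
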