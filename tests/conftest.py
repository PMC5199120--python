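import numpy as np
import pytest

from carousel.params import Abundances, KineticParameters
from carousel.network import build_network


@pytest.fixture(scope="session")
def reference_params():
    return KineticParameters()


@pytest.fixture(scope="session")
def reference_abundances():
    return Abundances()


@pytest.fixture(scope="session")
def simplified_net(reference_params):
    return build_network("simplified", reference_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def random_parameters(rng, span_decades=4.0):
    """One random kinetic parameter set, log-uniform around the reference."""
    ref = KineticParameters()
    half = span_decades / 2.0
    vals = {nm: getattr(ref, nm) * 10.0 ** rng.uniform(-half, half)
            for nm in ref.to_dict()}
    return KineticParameters(**vals)
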