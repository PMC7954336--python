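import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from nfsim import (
    AxonGeometry,
    EightStateRates,
    KineticRates,
    PhosphoKinetics,
    SixPhosphoRates,
    build_profile,
)


@pytest.fixture(scope="session")
def base_rates():
    """Canonical six-state rates."""
    return KineticRates()


@pytest.fixture(scope="session")
def phospho_internode():
    return PhosphoKinetics(gamma_ph=0.8, gamma_de=0.1)


@pytest.fixture(scope="session")
def phospho_node():
    return PhosphoKinetics(gamma_ph=0.1, gamma_de=0.8)


@pytest.fixture(scope="session")
def eight_internode(phospho_internode):
    return EightStateRates(gamma_on2=5.16e-3, phospho=phospho_internode)


@pytest.fixture(scope="session")
def eight_node(phospho_node):
    return EightStateRates(gamma_on2=6.01e-2, phospho=phospho_node)


@pytest.fixture(scope="session")
def geometry():
    return AxonGeometry()


@pytest.fixture(scope="session")
def uniform_fast_profile():
    """Spatially uniform profile with fast-relaxing rates.

    Node and internode rate sets are identical, and every relaxation
    time is short, so Monte Carlo runs equilibrate within minutes of
    model time.  Used for statistical invariants that do not depend on
    the canonical (slow) parameter values.
    """
    rates = EightStateRates(
        base=KineticRates(gamma_off=4.45e-3),
        gamma_on1=1e-2,
        gamma_on2=1e-2,
        phospho=PhosphoKinetics(gamma_ph=0.8, gamma_de=0.1),
    )
    return build_profile(AxonGeometry(), rates, rates)


def rng(seed=0):
    return np.random.default_rng(seed)
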