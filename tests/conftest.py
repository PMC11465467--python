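import numpy as np
import pytest

from spinsse import (
    Hyperfine,
    InteractionSet,
    Nucleus,
    RateScheme,
    SpinSystem,
    build_operators,
)
from spinsse.propagate import PropagatorConfig


@pytest.fixture(scope="session")
def one_nucleus_pair():
    """Singlet-born pair with one I=1/2 nucleus, isotropic 1 mT coupling."""
    system = SpinSystem(nuclei=(Nucleus("H1", 1, 0.5),))
    ints = InteractionSet(hyperfines=(Hyperfine.isotropic("H1", a_mT=1.0),))
    return system, ints


@pytest.fixture(scope="session")
def mixed_pair():
    """One ¹⁴N and one ¹H nucleus (dim 24) with anisotropic couplings."""
    system = SpinSystem(nuclei=(Nucleus("N", 1, 1.0), Nucleus("H", 2, 0.5)))
    ints = InteractionSet(
        field_mT=[0.1, 0.0, 0.5],
        hyperfines=(
            Hyperfine("N", np.diag([-2.0, -2.0, 30.0])),
            Hyperfine.isotropic("H", a_mT=0.4),
        ),
        j_MHz=2.0,
        dipolar_MHz=np.diag([1.0, 1.0, -2.0]),
    )
    return system, ints


@pytest.fixture(scope="session")
def four_proton_pair():
    """Four I=1/2 nuclei (Z=16, dim 64), the stochastic-sampling workhorse."""
    system = SpinSystem(
        nuclei=(
            Nucleus("H1", 1, 0.5),
            Nucleus("H2", 1, 0.5),
            Nucleus("H3", 2, 0.5),
            Nucleus("H4", 2, 0.5),
        )
    )
    ints = InteractionSet(
        field_mT=[0.0, 0.0, 0.5],
        hyperfines=(
            Hyperfine.isotropic("H1", a_mT=0.5),
            Hyperfine.isotropic("H2", a_mT=-0.3),
            Hyperfine.isotropic("H3", a_mT=0.4),
            Hyperfine.isotropic("H4", a_mT=0.2),
        ),
    )
    return system, ints


@pytest.fixture(scope="session")
def fast_config():
    return PropagatorConfig(dt_ns=2.0)


@pytest.fixture(scope="session")
def sym_rates():
    return RateScheme.symmetric(1.0)


@pytest.fixture(scope="session")
def ops_one(one_nucleus_pair):
    return build_operators(one_nucleus_pair[0])
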