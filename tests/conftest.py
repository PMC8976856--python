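import numpy as np
import pytest

import cryptdyn as cd


@pytest.fixture
def standard_spec() -> cd.ModelSpec:
    """Crypt model at the standard parametrisation: steady state (100, 1000)."""
    return cd.ModelSpec(topology="delta_of_D", beta=1.0, omega=0.1,
                        delta=cd.piecewise_linear(0.9, 1e-4, 2.0))


@pytest.fixture
def escape_spec() -> cd.ModelSpec:
    """Unbounded growth: differentiation saturates at 1.0 below beta=1.1."""
    return cd.ModelSpec(topology="delta_of_D", beta=1.1, omega=0.1,
                        delta=cd.piecewise_linear(0.9, 1e-4, 1.0))


@pytest.fixture(scope="session")
def random_stable_set() -> list:
    return cd.random_stable_specs(50, seed=20260923)


def nontrivial(spec: cd.ModelSpec) -> cd.EquilibriumReport:
    reps = [r for r in cd.steady_states(spec) if r.kind == "nontrivial"]
    assert reps, "expected a non-trivial steady state"
    return reps[0]


@pytest.fixture
def get_nontrivial():
    return nontrivial
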