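import numpy as np
import pytest
from hypothesis import settings

import thermokin as tk

# deterministic property tests, no on-disk example database
settings.register_profile("default", database=None, derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def two_state():
    """A<->B with k=(2,1): the analytically solvable relaxation toy."""
    return tk.fixture_network("two_state")


@pytest.fixture(scope="session")
def triangle():
    """Cyclic A<->B<->C<->A: one Wegscheider constraint."""
    return tk.fixture_network("triangle")


@pytest.fixture(scope="session")
def dimerization():
    """2A<->B: nonlinear kinetics with an analytic steady state."""
    return tk.fixture_network("dimerization")


@pytest.fixture(scope="session")
def chain3():
    """A<->B<->C<->D: the calibration workhorse (6 free parameters)."""
    return tk.fixture_network("chain3")


@pytest.fixture(scope="session")
def paper_hyper():
    """The reference forward-rate hyperparameter set."""
    return tk.ArrheniusHyperparams(kappa0=-5.1010, tau=1.8990, lam=0.7409)


@pytest.fixture(scope="session")
def toy_hyper():
    """Hyperparameters elicited for the O(1)-rate toy fixtures."""
    return tk.elicit_arrhenius_hyperparams(0.01, 100.0)


@pytest.fixture(scope="session")
def var_hyper():
    return tk.VarianceHyperparams(alpha=3.0, b=1.0)


def make_context(fixture, var_hyper, arr_hyper, sigma, seed, Q=6, kind="logarithmic"):
    """Generate one noisy study on a fixture and bundle the posterior context."""
    net, _, ktrue, design = fixture
    scheme = tk.SamplingScheme(kind=kind, Q=Q, t_max=design.t_max)
    ss = np.random.SeedSequence(seed)
    s_data, s_mem = ss.spawn(2)
    data = tk.generate_measurements(
        net, ktrue, design, tk.NoiseModel(sigma=sigma), s_data, scheme=scheme
    )
    ctx = tk.build_context(net, data.design, data, var_hyper, arr_hyper)
    return net, ktrue, data, ctx, s_mem
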