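import numpy as np
import pytest

import lamdec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """Columnar 24-neuron single-SF session shared by read-only tests."""
    cfg = lamdec.SessionConfig(n_neurons=24, sf_set=(2.0,),
                               reps_per_direction=5, seed=3)
    return lamdec.generate_session(cfg)


@pytest.fixture(scope="session")
def small_model(small_session):
    s = small_session
    return lamdec.estimate_laminar_model(
        s.lfp, s.trials["onset"].values[: s.config.n_lfp_trials])


@pytest.fixture(scope="session")
def small_metrics(small_session, small_model):
    return lamdec.compute_metrics(small_session, small_model)
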