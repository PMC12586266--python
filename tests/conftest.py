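import numpy as np
import pytest

import neuram as na


@pytest.fixture(scope="session")
def analytic_triple():
    return na.analytic_parabolic_neuram()


@pytest.fixture(scope="session")
def parabolic_batch():
    spec, dist = na.get_model("parabolic")
    return na.make_dataset(spec, dist, 256, seed=11)


@pytest.fixture(scope="session")
def sine_parabolic_neuram():
    """One trained reduction of sin(x1^2+x2) on U([0,1]^2), N=1000.

    Shared across tests: training is the expensive step, and several
    independent properties (errors, decoder range, loss trend) are checked
    on the same realization.
    """
    spec, dist = na.get_model("sine_parabolic")
    data = na.make_dataset(spec, dist, 1000, seed=101)
    nam = na.train_neuram(data, na.NetworkArchitecture(),
                          na.TrainingConfig(epochs=2000, seed=1, restarts=2))
    return spec, dist, nam


@pytest.fixture(scope="session")
def hartmann_neuram():
    """One trained reduction of the Hartmann mean-velocity output, N=1000."""
    spec, dist = na.get_model("hartmann_u")
    data = na.make_dataset(spec, dist, 1000, seed=42)
    nam = na.train_neuram(data, na.NetworkArchitecture(),
                          na.TrainingConfig(epochs=2000, seed=1, restarts=2))
    return spec, dist, nam
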