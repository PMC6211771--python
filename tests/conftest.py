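import numpy as np
import pytest

from mtfano.core import GainModelParams, TuningCurveFit
from mtfano.synthetic_data import SyntheticConfig, generate_trial_counts

GRID13 = tuple(float(d) for d in range(-90, 91, 15))
GRID24 = tuple(float(d) for d in range(-180, 180, 15))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def poisson_like_counts():
    """alpha=1, var_g=0: counts whose Fano factor is ~1 at every direction."""
    cfg = SyntheticConfig(
        n_neurons=3, n_trials=400, direction_grid=GRID13,
        gain_params=GainModelParams(1.0, 0.0),
        tuning=TuningCurveFit(5.0, 20.0, 2.0, 0.0), seed=7)
    return generate_trial_counts(cfg)
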