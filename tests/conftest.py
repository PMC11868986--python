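import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from regsnap.motif_core import PWM, BackgroundModel
from regsnap.synthetic_data import simulate_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_bg():
    return BackgroundModel.uniform()


@pytest.fixture
def small_pwm():
    """Length-3 PWM with informative columns."""
    return PWM("small", np.array([
        [0.7, 0.1, 0.1, 0.1],
        [0.1, 0.6, 0.2, 0.1],
        [0.05, 0.05, 0.8, 0.1],
    ]))


def random_pwm(rng, length, name="rand"):
    return PWM(name, rng.dirichlet(np.full(4, 0.8), size=length))


@pytest.fixture(scope="session")
def default_scenario(tmp_path_factory):
    """One default synthetic scenario shared by read-only tests."""
    outdir = tmp_path_factory.mktemp("scenario")
    manifest, paths = simulate_scenario(outdir, seed=11)
    return manifest, paths
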