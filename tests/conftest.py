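import numpy as np
import pytest

from t1dsim.experiments import (TWO_CLONE_PRESETS, run_two_clone,
                                sweep_avidity_killing)
from t1dsim.model_core import OneCloneParams, ReducedParams, TwoCloneParams


@pytest.fixture(scope="session")
def default_sweep():
    """The default 40x40 avidity x killing landscape (shared; ~1 min)."""
    return sweep_avidity_killing()


@pytest.fixture(scope="session")
def two_clone_runs():
    """All three two-clone presets at the default 12-year horizon."""
    return {name: run_two_clone(name) for name in TWO_CLONE_PRESETS}


@pytest.fixture()
def one_clone_params():
    return OneCloneParams()


@pytest.fixture()
def reduced_params():
    return ReducedParams()


@pytest.fixture()
def two_clone_params():
    return TwoCloneParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
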