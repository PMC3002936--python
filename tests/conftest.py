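import numpy as np
import pytest

import srsync as ss


@pytest.fixture
def rng():
    return np.random.default_rng(20101216)


@pytest.fixture(scope="session")
def default_grid():
    return ss.make_frequency_grid(srate=250.0)


@pytest.fixture(scope="session")
def small_config():
    """Two-source, reduced-trial configuration for fast end-to-end tests."""
    return ss.default_config(
        n_subjects=3,
        n_trials=40,
        sources=("R_STG", "L_SFG"),
        reset_params={
            "R_STG": ss.SRProfileParams(0.2, 2.5, 1.0),
            "L_SFG": ss.SRProfileParams(0.2, 2.5, 1.0),
        },
    )
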