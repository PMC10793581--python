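import numpy as np
import pytest

import dmsdecode as d
from dmsdecode.task import trials_to_frame


@pytest.fixture(scope="session")
def session600():
    """One standard 600-trial synthetic session (default study conditions)."""
    cfg = d.default_config(n_trials=600, seed=11)
    events, trials = d.generate_session(cfg)
    return cfg, events, trials_to_frame(trials)


@pytest.fixture(scope="session")
def correct_tensor(session600):
    """Correct-trial rate tensor over the test epoch (150/50 ms binning)."""
    cfg, events, tf = session600
    tfc = tf[tf["correct"]].reset_index(drop=True)
    tensor = d.bin_firing_rates(
        events, tfc, t_range_ms=(2300.0, 3000.0), n_channels=cfg.n_channels
    )
    return cfg, tensor, tfc


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
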