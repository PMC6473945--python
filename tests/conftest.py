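import numpy as np
import pytest

from clexsaxs.formfactor import BrokenRodParams
from clexsaxs.saxs_io import subtract_buffer, to_kratky
from clexsaxs.synthetic import default_q_grid, render_frames, scenario


@pytest.fixture(scope="session")
def q_grid():
    return default_q_grid()


@pytest.fixture(scope="session")
def full_gel_params():
    """pH 7.0 fully equilibrated gel: 0.9 nm chains + 2.9 nm junction
    zones at 80% weight fraction."""
    traj = scenario("pH7.0")
    return traj.params_at(36000.0)


@pytest.fixture(scope="session")
def single_chain_params():
    """Initial single-coil state: 0.2 nm cross-section."""
    return BrokenRodParams(rc1=0.2, k1=1.0, const=0.01, n_components=1)


def render_subtracted_profile(time_s, seed, noise_level=None, scenario_name="pH7.0"):
    """One buffer-subtracted Kratky profile from a preset trajectory."""
    traj = scenario(scenario_name)
    kwargs = {} if noise_level is None else {"noise_level": noise_level}
    frames, buf = render_frames(traj, [time_s], seed=seed, **kwargs)
    return to_kratky(subtract_buffer(frames[0], buf))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
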