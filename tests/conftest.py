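import numpy as np
import pytest

from gravipursuit.design import TrialCondition
from gravipursuit import trajectory as traj

#: the full stimulus design grid (gravity, v_yi, v_xi)
DESIGN_CELLS = [(g, vy, vx)
                for g in (0.7, 0.85, 1.0, 1.15, 1.3, -1.0)
                for vy in (4.5, 6.0)
                for vx in (3.0, 4.0)]


def make_condition(gravity=1.0, vx=3.0, vy=6.0, occ_category="long",
                   occ_fraction=0.475, trial_index=0):
    return TrialCondition(block_id=1, block_type="main", gravity_mult=gravity,
                          v_xi=vx, v_yi=vy, occ_category=occ_category,
                          occ_fraction=occ_fraction, rep_index=0,
                          trial_index=trial_index)


@pytest.fixture(scope="session")
def design_cells():
    return DESIGN_CELLS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def target_speed_fn(params):
    """Analytic target tangential speed as a callable over times."""
    return lambda t: traj.speed(params, np.clip(np.asarray(t, dtype=float),
                                                0.0, None))
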