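import numpy as np
import pytest

from motorkin.segmentation import Trajectory2D
from motorkin.synthetic import TwoStateTrajParams, simulate_two_state_trajectory


@pytest.fixture(scope="session")
def front_head_params() -> TwoStateTrajParams:
    """Moderate-size two-state trajectory parameters (20 kHz, 160/11 ms)."""
    return TwoStateTrajParams(
        frame_rate=20000.0,
        mean_bound_dwell=0.160,
        mean_unbound_dwell=0.011,
        n_frames=400_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def front_head_sim(front_head_params):
    """(trajectory, ground-truth segmentation) shared across tests."""
    return simulate_two_state_trajectory(front_head_params)


def make_step_trajectory(
    n: int,
    step_frame: int,
    step_on: float,
    noise: float = 0.0,
    frame_rate: float = 20000.0,
    seed: int = 0,
) -> Trajectory2D:
    """A single noiseless/noisy on-axis step at ``step_frame``."""
    rng = np.random.default_rng(seed)
    on = np.zeros(n)
    on[step_frame:] = step_on
    off = np.zeros(n)
    if noise > 0:
        on = on + rng.standard_normal(n) * noise
        off = off + rng.standard_normal(n) * noise
    return Trajectory2D.from_positions(on, off, frame_rate)
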