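import numpy as np
import pandas as pd
import pytest

from clonalfish import SimConfig


def make_grouped_data(
    rng: np.random.Generator,
    n_groups: int,
    reps,
    v_id: float = 1.0,
    v_res: float = 1.0,
    beta_x: float = 0.0,
) -> pd.DataFrame:
    """Random-intercept data with an optional within-group covariate."""
    if np.isscalar(reps):
        reps = np.full(n_groups, reps, dtype=int)
    u = rng.normal(0.0, np.sqrt(v_id), n_groups)
    rows = []
    for i in range(n_groups):
        for _ in range(int(reps[i])):
            x = rng.normal()
            rows.append(
                {
                    "g": f"g{i:03d}",
                    "x": x,
                    "y": beta_x * x + u[i] + rng.normal(0.0, np.sqrt(v_res)),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def scaled_traj_config() -> SimConfig:
    """Trajectory-friendly config: coarse time step, minutes-long phases."""
    return SimConfig(
        n_individuals=6,
        n_days_behavior=4,
        step_s=1.0,
        activity_phase_h=0.05,   # 180 steps
        feeding_phase_h=0.05,
    )
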