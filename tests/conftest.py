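import numpy as np
import pandas as pd
import pytest

from mircog import simulate
from mircog.maze import PoolGeometry, Trajectory


@pytest.fixture
def geometry() -> PoolGeometry:
    return PoolGeometry()


@pytest.fixture
def null_cohort():
    """Small two-group cohort with no planted effect."""
    spec = simulate.SimCohortSpec(n_cases=10, n_controls=10, n_features=80,
                                  log2_effect=0.0, seed=42)
    return simulate.simulate_cohort_counts(spec)


@pytest.fixture
def effect_cohort():
    """Cohort with a strong planted signature effect."""
    spec = simulate.SimCohortSpec(n_cases=20, n_controls=20, n_features=80,
                                  log2_effect=1.5, seed=7)
    return simulate.simulate_cohort_counts(spec)


def straight_trajectory(geometry: PoolGeometry, n: int = 30,
                        start=(-50.0, 0.0), end=None) -> Trajectory:
    """Constant-speed straight swim from start to the platform (or end)."""
    if end is None:
        end = geometry.platform_center
    t = np.linspace(0.0, 5.0, n)
    x = np.linspace(start[0], end[0], n)
    y = np.linspace(start[1], end[1], n)
    return Trajectory(trial_id="straight", t=t, x=x, y=y, geometry=geometry)
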