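import numpy as np
import pytest

from dissolvekit.profiles import DissolutionProfile

STANDARD_GRID = np.array([0.0, 5.0, 10.0, 15.0, 30.0, 45.0, 60.0])


@pytest.fixture
def grid():
    return STANDARD_GRID.copy()


@pytest.fixture
def fast_profile(grid):
    """First-order-like fast release (near-complete by 15 min)."""
    return DissolutionProfile("fast", grid, 100.0 * (1.0 - np.exp(-0.449 * grid)))


@pytest.fixture
def slow_profile(grid):
    """First-order slow release, ~50% dissolved at 60 min."""
    return DissolutionProfile("slow", grid, 100.0 * (1.0 - np.exp(-0.012 * grid)))


def random_monotone_profile(rng: np.random.Generator, n_points: int = 6) -> DissolutionProfile:
    """Random strictly-increasing-time, non-decreasing cumulative profile."""
    times = np.concatenate([[0.0], np.sort(rng.uniform(1.0, 90.0, n_points - 1))])
    increments = rng.uniform(0.0, 30.0, n_points - 1)
    dissolved = np.concatenate([[0.0], np.cumsum(increments)])
    dissolved = dissolved / max(dissolved[-1], 1.0) * rng.uniform(40.0, 100.0)
    return DissolutionProfile("rand", times, dissolved)
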