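import numpy as np
import pytest
from hypothesis import settings

from deerkin.forward import (
    BackgroundParams,
    DistanceDistribution,
    compose_trace,
    default_time_grid,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def t_grid():
    """Acquisition-like grid: 12 ns steps to 6.5 us."""
    return default_time_grid(6.5)


@pytest.fixture(scope="session")
def bimodal_truth():
    """Bimodal distribution of the protein-bound undamaged duplex."""
    return DistanceDistribution.from_arrays(
        [0.25, 0.75], [3.94, 4.60], [0.36, 0.34]
    )


@pytest.fixture(scope="session")
def default_bg():
    return BackgroundParams(alpha=0.1, xi=1.03)


@pytest.fixture(scope="session")
def noiseless_trace(bimodal_truth, default_bg, t_grid):
    return compose_trace(bimodal_truth, 0.3, default_bg, 1.0, t_grid)
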