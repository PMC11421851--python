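"""Shared fixtures.

The default-network reach solutions are expensive (N=200 iLQR solves), so
they are computed once per session and shared between the experiment-level
and acceptance tests.
"""

import numpy as np
import pytest

from prepctrl import experiments as ex


@pytest.fixture(scope="session")
def isn200():
    """Default inhibition-stabilized plant (N=200, seed 0)."""
    return ex.default_isn(n=200, seed=0)


@pytest.fixture(scope="session")
def delay_sweep(isn200):
    """Optimal single reaches to all 8 targets at zero and 300 ms delays."""
    return ex.run_delay_sweep(isn200, delays=(0.0, 300.0))


@pytest.fixture(scope="session")
def single_solutions_300(delay_sweep):
    sols = [delay_sweep.solutions[(300.0, j)] for j in range(8)]
    assert all(s.converged or not s.stalled for s in sols)
    return sols


@pytest.fixture(scope="session")
def sequence_result(isn200, single_solutions_300):
    """Sequence experiment (2 target pairs, double + compound variants),
    reusing the single-reach solutions for subspace identification."""
    return ex.run_sequence_experiment(
        isn200, pairs=[(0, 3), (4, 1)], single_solutions=single_solutions_300
    )
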