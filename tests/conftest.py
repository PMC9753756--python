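"""Shared fixtures: small equilibrated melts reused across test modules.

Simulation fixtures are session-scoped because the kMC kernel is
numba-compiled on first use and short equilibration runs dominate the
suite's runtime.
"""

import numpy as np
import pytest

from ringmelt.kmc_engine import SimulationParams, run
from ringmelt.melt_state import build_linear_melt, build_ring_melt


@pytest.fixture(scope="session")
def small_ring_melt():
    """Fully flexible ring melt at melt density, pre-equilibrated."""
    cfg = build_ring_melt(M=8, N=48, occupancy=1.25, kappa_bend=0.0, seed=11)
    traj = run(cfg, SimulationParams(sweeps=4000, snapshot_every=2000, seed=101))
    return traj.info["final_config"]


@pytest.fixture(scope="session")
def ring_melt_trajectory():
    """Short evenly sampled trajectory of a flexible ring melt."""
    cfg = build_ring_melt(M=8, N=48, occupancy=1.25, kappa_bend=0.0, seed=11)
    warm = run(cfg, SimulationParams(sweeps=3000, snapshot_every=3000, seed=7))
    return run(warm.info["final_config"],
               SimulationParams(sweeps=3000, snapshot_every=100, seed=13))


@pytest.fixture(scope="session")
def linear_melt_trajectory():
    """Short trajectory of a flexible linear melt (Kuhn-length tests)."""
    cfg = build_linear_melt(M=8, N=60, occupancy=1.25, kappa_bend=0.0, seed=5)
    warm = run(cfg, SimulationParams(sweeps=3000, snapshot_every=3000, seed=9))
    return run(warm.info["final_config"],
               SimulationParams(sweeps=2000, snapshot_every=200, seed=15))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
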