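"""Standard measurement protocols: build, equilibrate, sample, measure.

These are the package's canonical study conditions for reproducing the
equilibrium calibration of the lattice model at melt density
(rho a^3 = 1.77, i.e. 1.25 monomers per fcc site).  Melts are built from
the slack-rich racetrack initial state and equilibrated from the mobile
side; the equilibration lengths are chosen from the convergence of
<b> and <cos theta> (local quantities plateau within a few hundred
thousand sweeps; sampling then extends over a comparable window so the
slow collective orientation fluctuations average out).
"""

from __future__ import annotations

import numpy as np

from .calibration import mean_bond_cosine, mean_bond_length
from .kmc_engine import SimulationParams, run
from .melt_state import Trajectory, build_linear_melt, build_ring_melt

__all__ = ["equilibrium_angle_statistics", "ideal_chain_angle_counts"]


def equilibrium_angle_statistics(
    kappa_bend: float,
    topology: str = "ring",
    M: int = 16,
    N: int = 100,
    occupancy: float = 1.25,
    equil_sweeps: int = 1_000_000,
    sample_sweeps: int = 600_000,
    n_samples: int = 12,
    seed: int = 0,
) -> dict:
    """Equilibrium <b>, <cos theta> and acceptance rate of one melt.

    Builds the melt, runs ``equil_sweeps`` of kMC without recording, then
    samples ``n_samples`` snapshots over ``sample_sweeps`` more sweeps.
    Returns a dict with keys ``b``, ``cos_theta``, ``acceptance_rate``,
    ``M``, ``N``, ``box`` and the sampling trajectory.
    """
    ss = np.random.SeedSequence([int(seed), 0xCA11])
    s_build, s_equil, s_sample = (int(x % (2 ** 31))
                                  for x in ss.generate_state(3))
    builder = build_ring_melt if topology == "ring" else build_linear_melt
    cfg = builder(M=M, N=N, occupancy=occupancy, kappa_bend=kappa_bend,
                  seed=s_build)
    warm = run(cfg, SimulationParams(sweeps=equil_sweeps,
                                     snapshot_every=equil_sweeps,
                                     seed=s_equil))
    traj = run(warm.info["final_config"],
               SimulationParams(sweeps=sample_sweeps,
                                snapshot_every=max(1, sample_sweeps // n_samples),
                                seed=s_sample))
    return {
        "b": mean_bond_length(traj, skip=1),
        "cos_theta": mean_bond_cosine(traj, skip=1),
        "acceptance_rate": traj.info["acceptance_rate"],
        "M": M, "N": N, "box": cfg.box,
        "occupancy": cfg.occupancy,
        "trajectory": traj,
    }


def ideal_chain_angle_counts(
    kappa_bend: float,
    N: int = 200,
    sweeps: int = 30_000,
    n_samples: int = 60,
    seed: int = 0,
) -> dict:
    """Angle histogram of a single phantom chain (excluded volume off).

    Counts the bending angles over *adjacent* effective-bond pairs, whose
    stationary distribution is exactly the discrete Boltzmann form
    ``P(cos) ~ Omega(cos) exp(kappa cos)`` (the angles across stored-length
    units carry a doubled Boltzmann weight and are excluded here).
    Returns {cos: count}.
    """
    from .fcc_lattice import neighbor_vectors
    from .melt_state import MeltConfiguration

    ss = np.random.SeedSequence([int(seed), 0x1DEA])
    s_run = int(ss.generate_state(1)[0] % (2 ** 31))
    nei = neighbor_vectors()
    rng = np.random.default_rng(int(ss.generate_state(2)[1] % (2 ** 31)))
    steps = nei[rng.integers(0, 12, size=N - 1)]
    pos = np.cumsum(np.vstack([[0, 0, 0], steps]), axis=0)
    L = 4 * N
    cfg = MeltConfiguration(coords=np.mod(pos, L),
                            chains=np.arange(N)[None, :],
                            box=(L, L, L), kappa_bend=kappa_bend,
                            topology="linear")
    traj = run(cfg, SimulationParams(sweeps=sweeps,
                                     snapshot_every=max(1, sweeps // n_samples),
                                     seed=s_run, excluded_volume=False))
    counts: dict[float, int] = {c: 0 for c in (1.0, 0.5, 0.0, -0.5, -1.0)}
    skip = n_samples // 3
    for s in range(skip, traj.n_snapshots):
        p = traj.coords[s]
        d = np.diff(p, axis=0)
        nz = (d ** 2).sum(axis=1) > 0
        m = nz[:-1] & nz[1:]
        cosv = (d[:-1][m] * d[1:][m]).sum(axis=1) / 2.0
        for c in cosv:
            counts[float(c)] += 1
    return counts
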