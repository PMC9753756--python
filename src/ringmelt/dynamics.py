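"""Mean-square displacement observables and reference theory curves.

Measured quantities (time- and ensemble-averaged over a trajectory of
unwrapped snapshots, lengths in a^2, lags in tau_MC):

* g1(tau) - monomer mean-square displacement;
* g3(tau) - chain centre-of-mass mean-square displacement;
* g2(tau) - monomer MSD in the centre-of-mass frame (g2 ~ g1 - g3;
  its long-time plateau, ~ 2 <R_g^2>, signals structural relaxation).

Reference curves encode the tree-like relaxation picture.  With exponents
nu (ring size), rho (backbone mass) and the tube-dilation parameter
theta in [0, 1] (0: fixed obstacles; 1: full constraint release), the
relaxation-time exponent is

    tau_r / tau_e = Z^(2 + rho_eff),   rho_eff = rho (1 - theta) + nu theta

so the intermediate-regime g1 power is 2 nu / (2 + rho_eff): 6/23 ~ 0.26
without dilation (nu = 1/3, rho = 5/9) and 2/7 ~ 0.29 at full dilation.
The diffusion coefficient scales as D ~ R^2 / tau_r ~ N^(2 nu - 2 - rho_eff).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fcc_lattice import A
from .melt_state import MeltConfiguration, Trajectory
from .kmc_engine import SimulationParams, pin_rings, run

__all__ = [
    "MsdCurves",
    "msd_curves",
    "theory_curves",
    "intermediate_g1_exponent",
    "relaxation_time",
    "diffusion_exponent",
    "is_relaxed",
    "pinning_experiment",
]

NU_LATTICE_TREE = 1.0 / 3.0
RHO_LATTICE_TREE = 5.0 / 9.0


@dataclass
class MsdCurves:
    """Lag grid plus the three displacement curves of one run."""

    tau: np.ndarray
    g1: np.ndarray
    g2: np.ndarray
    g3: np.ndarray
    rg2: float                      # ensemble <R_g^2> (a^2)
    label: dict = field(default_factory=dict)


def _lag_grid(n_snap: int, per_decade: int = 8) -> np.ndarray:
    if n_snap < 2:
        raise ValueError("need at least 2 snapshots for displacements")
    lags = np.unique(np.rint(
        10 ** np.linspace(0, np.log10(n_snap - 1),
                          max(2, int(np.log10(max(n_snap - 1, 2)) * per_decade)))
    ).astype(int))
    return lags[lags >= 1]


def msd_curves(traj: Trajectory, restrict_to_unpinned: bool = True,
               per_decade: int = 8) -> MsdCurves:
    """Multi-tau displacement curves with overlapping time origins.

    Snapshots must be evenly spaced in time; lags follow a logarithmic
    grid.  With pinning, averages run over the non-pinned chains only.
    """
    cfg = traj.config
    if traj.n_snapshots < 2:
        raise ValueError("need at least 2 snapshots")
    dt = np.diff(traj.times)
    if not np.allclose(dt, dt[0]):
        raise ValueError("msd_curves requires an evenly spaced snapshot grid")
    chains = [c for c in range(cfg.n_chains)
              if not (restrict_to_unpinned and c in cfg.pinned)]
    if not chains:
        raise ValueError("no unpinned chains to average over")
    idx = np.concatenate([cfg.chains[c] for c in chains])
    pos = traj.coords[:, idx, :].astype(float) / A          # (S, n, 3), units a
    com = pos.reshape(len(traj.times), len(chains), cfg.chain_length, 3).mean(axis=2)
    rel = pos.reshape(len(traj.times), len(chains), cfg.chain_length, 3) \
        - com[:, :, None, :]
    lags = _lag_grid(traj.n_snapshots, per_decade)
    g1 = np.empty(len(lags))
    g2 = np.empty(len(lags))
    g3 = np.empty(len(lags))
    for k, lag in enumerate(lags):
        d = pos[lag:] - pos[:-lag]
        g1[k] = (d ** 2).sum(axis=-1).mean()
        dc = com[lag:] - com[:-lag]
        g3[k] = (dc ** 2).sum(axis=-1).mean()
        dr = rel[lag:] - rel[:-lag]
        g2[k] = (dr ** 2).sum(axis=-1).mean()
    rg2 = float((rel ** 2).sum(axis=-1).mean())
    return MsdCurves(tau=lags * float(dt[0]), g1=g1, g2=g2, g3=g3, rg2=rg2,
                     label={"kappa": cfg.kappa_bend, "N": cfg.chain_length,
                            "pinned": len(cfg.pinned)})


# ---------------------------------------------------------------------------
# theory reference curves
# ---------------------------------------------------------------------------

def _rho_eff(rho: float, nu: float, theta: float) -> float:
    return rho * (1.0 - theta) + nu * theta


def intermediate_g1_exponent(nu: float = NU_LATTICE_TREE,
                             rho: float = RHO_LATTICE_TREE,
                             theta: float = 0.0) -> float:
    """Intermediate-regime g1 power 2 nu / (2 + rho_eff).

    0.26 for the undilated lattice tree (theta = 0), about 0.29 (= 2/7)
    at full tube dilation (theta = 1, nu = 1/3).
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must be in [0, 1]")
    return 2.0 * nu / (2.0 + _rho_eff(rho, nu, theta))


def relaxation_time(Z: float, theta: float = 0.0,
                    rho: float = RHO_LATTICE_TREE, tau_e: float = 1.0,
                    nu: float = NU_LATTICE_TREE) -> float:
    """Global relaxation time tau_r = tau_e * Z^(2 + rho_eff)."""
    if Z <= 0:
        raise ValueError("Z must be positive")
    return tau_e * Z ** (2.0 + _rho_eff(rho, nu, theta))


def diffusion_exponent(theta: float = 0.0, nu: float = NU_LATTICE_TREE,
                       rho: float = RHO_LATTICE_TREE) -> float:
    """Exponent of D ~ N^x from D ~ R^2 / tau_r: x = 2 nu - 2 - rho_eff.

    -17/9 for the undilated lattice tree; -5/3 at full dilation.
    """
    return 2.0 * nu - 2.0 - _rho_eff(rho, nu, theta)


def theory_curves(Z: float, tau: np.ndarray, d_T: float = 1.0,
                  tau_e: float = 1.0, nu: float = NU_LATTICE_TREE,
                  rho: float = RHO_LATTICE_TREE, theta: float = 0.0,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Smooth three-regime reference curves for g1 and g3.

    Regimes: Rouse-like (g1 ~ tau^1/2, g3 ~ tau) below tau_e; tree mass
    transport with the exponents above between tau_e and tau_r; free
    diffusion beyond tau_r, with g1(tau_e) ~ d_T^2 and g1(tau_r) ~ R^2 ~
    d_T^2 Z^(2 nu).  The multiplicative crossover construction
    x^a (1+x)^(b-a) (1+x/x_r)^(1-b) fixes the limiting exponents; the O(1)
    crossover coefficients are a smooth-interpolation choice of this
    package, not a fitted quantity.
    """
    x = np.asarray(tau, dtype=float) / tau_e
    alpha = intermediate_g1_exponent(nu, rho, theta)
    re = _rho_eff(rho, nu, theta)
    xr = Z ** (2.0 + re)
    g1 = d_T ** 2 * x ** 0.5 * (1 + x) ** (alpha - 0.5) * (1 + x / xr) ** (1 - alpha)
    beta = (2 * nu + 1.0) / (2.0 + re)
    g3 = (d_T ** 2 / Z) * x * (1 + x) ** (beta - 1.0) * (1 + x / xr) ** (1 - beta)
    return g1, g3


# ---------------------------------------------------------------------------
# relaxation diagnostic and pinning experiments
# ---------------------------------------------------------------------------

def is_relaxed(curves: MsdCurves, slope_tol: float = 0.05,
               level_tol: float = 0.20) -> bool:
    """Structural-relaxation criterion: g2 has a late-time plateau.

    Operationally: the log-log slope of g2 over the last decade of lags is
    below ``slope_tol`` and the plateau level is within ``level_tol`` of
    2 <R_g^2>.
    """
    tau, g2 = curves.tau, curves.g2
    last = tau >= tau.max() / 10.0
    if last.sum() < 2:
        return False
    slope = np.polyfit(np.log(tau[last]), np.log(np.maximum(g2[last], 1e-300)), 1)[0]
    level = g2[last].mean()
    return bool(slope < slope_tol
                and abs(level - 2 * curves.rg2) <= level_tol * 2 * curves.rg2)


def pinning_experiment(config: MeltConfiguration, pin_fractions,
                       params: SimulationParams,
                       freeze_threshold: float = 0.5):
    """Run one melt at several pinning fractions and collect g3 curves.

    For each f_p, a fresh copy of the melt has floor(f_p M) rings frozen
    (uniformly at random, seeded per fraction) and is evolved with
    ``params``; g3 is averaged over the unpinned rings.  A curve is
    flagged frozen when its late-time g3 stays below ``freeze_threshold``
    times 2 <R_g^2>.  f_p = 1 yields no mobile rings and an empty, flagged
    entry.

    Returns a list of dicts: {f_p, curves, frozen}.
    """
    results = []
    for i, f_p in enumerate(pin_fractions):
        pinned = pin_rings(config, f_p,
                           np.random.default_rng([params.seed, 17, i]))
        if len(pinned.pinned) >= config.n_chains:
            results.append({"f_p": float(f_p), "curves": None, "frozen": True})
            continue
        p = SimulationParams(sweeps=params.sweeps,
                             snapshot_every=params.snapshot_every,
                             seed=params.seed + 1000 * i + 7,
                             excluded_volume=params.excluded_volume)
        traj = run(pinned, p)
        curves = msd_curves(traj, restrict_to_unpinned=True)
        late = curves.tau >= curves.tau.max() / 10.0
        frozen = bool(curves.g3[late].mean()
                      < freeze_threshold * 2 * curves.rg2 / config.chain_length)
        results.append({"f_p": float(f_p), "curves": curves, "frozen": frozen})
    return results
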