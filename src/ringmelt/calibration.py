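"""Entanglement-unit calibration of stored-length lattice melts.

The melt's mesoscopic description rests on a small set of derived scales:

* mean effective bond length ``<b>`` (stored-length units have length 0);
* Kuhn length ``l_K``, from the large-separation plateau of the internal
  mean-square distances ``<R^2(l)> / l`` of *linear* chains;
* Kuhn segment density ``rho_K = rho <b> / l_K`` and the dimensionless
  overlap number ``n_K = rho_K l_K^3``;
* entanglement length ``L_e`` from the Uchida-Grest-Everaers crossover

      L_e / l_K = (0.06 n_K)^-2 + (0.06 n_K)^-(2/5)

  interpolating between loosely entangled melts (exponent 2) and tightly
  entangled solutions (exponent 2/5);
* tube diameter ``d_T = sqrt(l_K L_e / 6)``, the mean gyration radius of
  an ideal strand of contour length L_e;
* entanglement time ``tau_e``, where the monomer mean-square displacement
  of a linear melt reaches ``d_T^2``.

Chain contour lengths are expressed as entanglement counts ``Z = L / L_e``
(and ``z = l / L_e`` for subchains).  All lengths are in units of the fcc
bond length ``a``; densities in ``a^-3``; times in tau_MC.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .fcc_lattice import A
from .melt_state import Trajectory, _min_image

__all__ = [
    "EntanglementUnits",
    "REFERENCE_CALIBRATION",
    "MELT_DENSITY_A3",
    "mean_bond_length",
    "mean_bond_cosine",
    "internal_distances",
    "estimate_kuhn_length",
    "entanglement_length",
    "tube_diameter",
    "entanglement_time",
    "validate_crossover_formula",
]

#: monomer number density of the reference melt state, rho * a^3
MELT_DENSITY_A3 = 1.77

# Published equilibrium calibration of this lattice-polymer model at
# rho a^3 = 1.77, indexed by bending stiffness kappa_bend.  Columns:
# acceptance rate, <cos theta> linear / ring, <b>/a, l_K/a, n_K,
# L_e/a, N_e, d_T/a, tau_e/tau_MC.
REFERENCE_CALIBRATION = {
    0.0: dict(acc_rate=0.069, cos_lin=0.187, cos_ring=0.171, b=0.731,
              l_K=1.440, n_K=2.679, L_e=58.738, N_e=80.379, d_T=3.755,
              tau_e=15.0e4),
    1.0: dict(acc_rate=0.048, cos_lin=0.476, cos_ring=0.447, b=0.696,
              l_K=2.194, n_K=5.920, L_e=20.708, N_e=29.764, d_T=2.752,
              tau_e=5.2e4),
    2.0: dict(acc_rate=0.036, cos_lin=0.670, cos_ring=0.635, b=0.669,
              l_K=3.393, n_K=13.620, L_e=8.759, N_e=13.088, d_T=2.226,
              tau_e=2.8e4),
}

# Uchida et al. crossover coefficient (dimensionless)
_UCHIDA_COEF = 0.06


def entanglement_length(l_K: float, n_K: float) -> float:
    """Entanglement length L_e (units of a) from the crossover formula.

    Parameters
    ----------
    l_K : Kuhn length in units of a.
    n_K : Kuhn segments per Kuhn volume, rho_K * l_K^3.
    """
    if l_K <= 0 or n_K <= 0:
        raise ValueError("l_K and n_K must be positive")
    x = _UCHIDA_COEF * n_K
    return l_K * (x ** -2.0 + x ** -0.4)


def tube_diameter(L_e: float, l_K: float) -> float:
    """Tube diameter: gyration radius of an ideal strand of length L_e."""
    if L_e <= 0 or l_K <= 0:
        raise ValueError("L_e and l_K must be positive")
    return float(np.sqrt(l_K * L_e / 6.0))


@dataclass
class EntanglementUnits:
    """Complete per-stiffness calibration record (lengths in a)."""

    kappa_bend: float
    b: float                    # mean effective bond length
    l_K: float                  # Kuhn length
    rho: float = MELT_DENSITY_A3   # monomer density * a^3
    tau_e: float = float("nan")    # entanglement time (tau_MC)

    def __post_init__(self) -> None:
        if not (self.b > 0 and self.l_K > 0 and self.rho > 0):
            raise ValueError("b, l_K and rho must be positive")

    # -- derived quantities ------------------------------------------------
    @property
    def rho_K(self) -> float:
        """Kuhn segment density rho <b> / l_K (a^-3)."""
        return self.rho * self.b / self.l_K

    @property
    def n_K(self) -> float:
        """Kuhn segments per Kuhn volume: rho_K l_K^3 = rho <b> l_K^2."""
        return self.rho_K * self.l_K ** 3

    @property
    def L_e(self) -> float:
        return entanglement_length(self.l_K, self.n_K)

    @property
    def N_e(self) -> float:
        """Monomers per entanglement length, L_e / <b>."""
        return self.L_e / self.b

    @property
    def d_T(self) -> float:
        return tube_diameter(self.L_e, self.l_K)

    # -- unit conversions --------------------------------------------------
    def Z(self, N: int) -> float:
        """Entanglements per chain of N monomers: Z = N <b> / L_e = N/N_e."""
        return N / self.N_e

    def z(self, contour: float) -> float:
        """Entanglement count of a subchain of contour length l (in a)."""
        return contour / self.L_e

    def in_tube_units(self, length: float) -> float:
        """A length (in a) expressed in tube diameters."""
        return length / self.d_T

    def as_dict(self) -> dict:
        d = asdict(self)
        d.update(rho_K=self.rho_K, n_K=self.n_K, L_e=self.L_e,
                 N_e=self.N_e, d_T=self.d_T)
        return d

    @classmethod
    def from_reference(cls, kappa_bend: float) -> "EntanglementUnits":
        """Units built from the published <b>, l_K calibration inputs."""
        row = REFERENCE_CALIBRATION[float(kappa_bend)]
        return cls(kappa_bend=float(kappa_bend), b=row["b"], l_K=row["l_K"],
                   tau_e=row["tau_e"])


def validate_crossover_formula(rtol: float = 0.005) -> bool:
    """Check the transcribed crossover expression against every reference
    (l_K, n_K) -> L_e triple.  Raises AssertionError beyond ``rtol``."""
    for kappa, row in REFERENCE_CALIBRATION.items():
        le = entanglement_length(row["l_K"], row["n_K"])
        if abs(le - row["L_e"]) / row["L_e"] > rtol:  # pragma: no cover
            raise AssertionError(
                f"crossover formula off at kappa={kappa}: {le} vs {row['L_e']}"
            )
    return True


# ---------------------------------------------------------------------------
# measurements on trajectories
# ---------------------------------------------------------------------------

def _chain_bonds(traj: Trajectory, snap: int, chain: int) -> np.ndarray:
    cfg = traj.config
    p = traj.coords[snap][cfg.chains[chain]]
    if cfg.topology == "ring":
        p = np.vstack([p, p[:1]])
    return np.diff(p, axis=0)


def mean_bond_length(traj: Trajectory, skip: int = 0) -> float:
    """Mean effective bond length <b> in units of a.

    Equals the fraction of non-zero bonds (bond lengths are 0 or a).
    """
    if traj.n_snapshots - skip < 1:
        raise ValueError("no snapshots to average over")
    vals = []
    for s in range(skip, traj.n_snapshots):
        for c in range(traj.config.n_chains):
            d = _chain_bonds(traj, s, c)
            vals.append(((d ** 2).sum(axis=1) > 0).mean())
    return float(np.mean(vals))


def mean_bond_cosine(traj: Trajectory, skip: int = 0) -> float:
    """Mean cosine of the bending angle, averaged per monomer.

    The angle at a monomer is taken between the nearest effective bonds on
    its two sides (zero-length bonds are skipped), matching the convention
    of the bending energy: both monomers of a stored-length pair see the
    same flanking bond pair.
    """
    if traj.n_snapshots - skip < 1:
        raise ValueError("no snapshots to average over")
    ring = traj.config.topology == "ring"
    N = traj.config.chain_length
    out = []
    for s in range(skip, traj.n_snapshots):
        for c in range(traj.config.n_chains):
            d = _chain_bonds(traj, s, c)
            nb = len(d)
            z = (d ** 2).sum(axis=1) == 0
            for q in range(N):
                j = q - 1
                if ring:
                    j %= nb
                elif j < 0:
                    continue
                if z[j]:
                    j = (j - 1) % nb if ring else j - 1
                    if j < 0:
                        continue
                k = q
                if not ring and k > nb - 1:
                    continue
                if z[k % nb]:
                    k = (k + 1) % nb if ring else k + 1
                    if not ring and k > nb - 1:
                        continue
                k %= nb
                if j == k:
                    continue
                out.append(float(d[j] @ d[k]) / 2.0)
    return float(np.mean(out))


def internal_distances(traj: Trajectory, skip: int = 0,
                       b: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Mean-square internal distances of linear chains.

    Returns (l, R2): contour separations ``l = n <b>`` (units of a) and
    ``<R^2(l)>`` (units of a^2) for every monomer separation n.
    """
    cfg = traj.config
    if cfg.topology != "linear":
        raise ValueError("internal distances are defined for linear melts")
    if b is None:
        b = mean_bond_length(traj, skip=skip)
    N = cfg.chain_length
    acc = np.zeros(N)
    cnt = np.zeros(N)
    for s in range(skip, traj.n_snapshots):
        for c in range(cfg.n_chains):
            p = traj.coords[s][cfg.chains[c]].astype(float) / A  # units of a
            for n in range(1, N):
                d = p[n:] - p[:-n]
                acc[n] += (d ** 2).sum(axis=1).mean()
                cnt[n] += 1
    n = np.arange(1, N)
    return n * b, acc[1:] / cnt[1:]


def estimate_kuhn_length(traj: Trajectory, skip: int = 0,
                         fit_window: tuple[float, float] = (150.0, 200.0),
                         ) -> tuple[float, dict]:
    """Kuhn length from the plateau of <R^2(l)> / l on linear chains.

    Fits a constant on the contour-separation window ``fit_window`` (units
    of a; defaults to the long-chain plateau window [150, 200]).  Returns
    ``(l_K, diagnostics)``; the fit is flagged unreliable when
    <R^2(l)> / l still drifts by more than 10% across the window (e.g. a
    rod, which has no plateau).
    """
    ell, r2 = internal_distances(traj, skip=skip)
    lo, hi = fit_window
    mask = (ell >= lo) & (ell <= hi)
    if mask.sum() < 3:
        raise ValueError(
            f"chains too short for the fit window [{lo}, {hi}]a "
            f"(max separation {ell.max():.1f}a)"
        )
    ratio = r2[mask] / ell[mask]
    l_K = float(ratio.mean())
    drift = float((ratio.max() - ratio.min()) / l_K)
    diag = {
        "window": (lo, hi),
        "n_points": int(mask.sum()),
        "drift": drift,
        "reliable": drift < 0.10,
        "stderr": float(ratio.std(ddof=1) / np.sqrt(mask.sum())),
    }
    return l_K, diag


def entanglement_time(tau: np.ndarray, g1: np.ndarray, d_T: float) -> float:
    """Solve g1(tau_e) = d_T^2 by log-log interpolation.

    ``tau``/``g1`` must be positive and ``g1`` monotone enough to bracket
    the crossing; raises if the curve never reaches d_T^2.
    """
    tau = np.asarray(tau, dtype=float)
    g1 = np.asarray(g1, dtype=float)
    ok = (tau > 0) & (g1 > 0)
    tau, g1 = tau[ok], g1[ok]
    target = d_T ** 2
    above = g1 >= target
    if not above.any() or above.all():
        raise ValueError("g1 curve does not bracket d_T^2")
    i = int(np.argmax(above))          # first sample at/above the target
    if i == 0:
        return float(tau[0])
    lt = np.log(tau[i - 1:i + 1])
    lg = np.log(g1[i - 1:i + 1])
    f = (np.log(target) - lg[0]) / (lg[1] - lg[0])
    return float(np.exp(lt[0] + f * (lt[1] - lt[0])))
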