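"""Single-conformation and ensemble structural observables of ring melts.

All operations take *unwrapped* coordinates in embedding units and report
lengths in units of the fcc bond length ``a`` (areas in ``a^2``), except
where noted.  Ensemble averages iterate over trajectory snapshots and
chains.

The shape analysis uses the gyration tensor; ring-specific size measures
are the squared gyration radius and the squared "magnetic" radius built
from the oriented area enclosed by the ring (sensitive to open loops, by
analogy with the far field of a current loop).  Contour-scale structure is
probed by the bond-vector correlation function c(l) and the mean contact
probability p_c(l).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .fcc_lattice import A
from .melt_state import Trajectory, _min_image, unwrap

__all__ = [
    "StaticSummary",
    "gyration_radius_sq",
    "gyration_tensor",
    "magnetic_radius_sq",
    "oriented_area",
    "bond_correlation",
    "double_fold_reference",
    "contact_probability",
    "fit_scaling",
    "static_summary",
]


def gyration_radius_sq(coords: np.ndarray) -> float:
    """Mean squared distance of monomers from their centre of mass (a^2)."""
    r = np.asarray(coords, dtype=float) / A
    r = r - r.mean(axis=0)
    return float((r ** 2).sum(axis=1).mean())


def gyration_tensor(coords: np.ndarray) -> np.ndarray:
    """Ordered eigenvalues (ascending) of the 3x3 gyration tensor (a^2).

    The trace equals the squared gyration radius.
    """
    r = np.asarray(coords, dtype=float) / A
    r = r - r.mean(axis=0)
    t = r.T @ r / len(r)
    return np.sort(np.linalg.eigvalsh(t))


def oriented_area(ring: np.ndarray) -> np.ndarray:
    """Oriented area vector A = 1/2 sum_i r_i x r_{i+1} of a closed ring.

    Translation invariant by ring closure; units a^2.
    """
    r = np.asarray(ring, dtype=float) / A
    if len(r) < 3:
        raise ValueError("ring needs at least 3 vertices")
    r = r - r.mean(axis=0)          # numerical conditioning only
    nxt = np.roll(r, -1, axis=0)
    return 0.5 * np.cross(r, nxt).sum(axis=0)


def magnetic_radius_sq(ring: np.ndarray) -> float:
    """Squared magnetic radius of a closed ring, R_m^2 = |A| / pi (a^2).

    The normalization is fixed by the circle limit: a planar circle of
    radius R has |A| = pi R^2 and hence R_m = R.  A symmetric figure-eight
    encloses zero oriented area and returns 0.
    """
    return float(np.linalg.norm(oriented_area(ring)) / np.pi)


# ---------------------------------------------------------------------------
# contour correlations
# ---------------------------------------------------------------------------

def double_fold_reference(z: float) -> float:
    """Bond correlation of an exactly double-folded filament of contour
    2 L_e at separation z = l / L_e:

        c(z) = (1 - 3z/2) / (1 - z/2)   for 0 < z < 1
        c(z) = -1                       for 1 <= z < 2

    continuous at z = 1; domain error outside (0, 2).
    """
    if not 0.0 < z < 2.0:
        raise ValueError("z must lie in (0, 2)")
    if z >= 1.0:
        return -1.0
    return (1.0 - 1.5 * z) / (1.0 - 0.5 * z)


def bond_correlation(traj: Trajectory, skip: int = 0,
                     b: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Normalized bond-vector correlation c(l) vs contour separation.

    Effective (non-zero) bonds are correlated at monomer-index separation
    n; the contour separation is reported as ``l = n <b>`` in units of a.
    Pairs in which either bond is a stored-length unit are skipped.
    Returns (l, c).
    """
    cfg = traj.config
    ring = cfg.topology == "ring"
    N = cfg.chain_length
    if b is None:
        from .calibration import mean_bond_length
        b = mean_bond_length(traj, skip=skip)
    nmax = N // 2 if ring else N - 2
    acc = np.zeros(nmax + 1)
    cnt = np.zeros(nmax + 1)
    for s in range(skip, traj.n_snapshots):
        for c in range(cfg.n_chains):
            p = traj.coords[s][cfg.chains[c]].astype(float)
            d = np.diff(np.vstack([p, p[:1]]), axis=0) if ring else np.diff(p, axis=0)
            d = d / A
            nz = (d ** 2).sum(axis=1) > 1e-9
            for n in range(1, nmax + 1):
                if ring:
                    d1, d2 = d, np.roll(d, -n, axis=0)
                    m = nz & np.roll(nz, -n)
                else:
                    d1, d2 = d[:-n], d[n:]
                    m = nz[:-n] & nz[n:]
                if m.sum() == 0:
                    continue
                acc[n] += (d1[m] * d2[m]).sum(axis=1).mean()
                cnt[n] += 1
    n = np.arange(1, nmax + 1)
    ok = cnt[1:] > 0
    return n[ok] * b, acc[1:][ok] / cnt[1:][ok]


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def contact_probability(traj: Trajectory, r_c: float = 1.0, skip: int = 0,
                        b: float | None = None):
    """Mean contact probability of ring monomer pairs vs contour separation.

    Two monomers are in contact when their minimum-image distance is at
    most ``r_c`` (units of a; default one lattice unit).  On a ring the
    contour separation of a pair is the shorter arc, min(n, N - n).

    Returns a dict with arrays:
      ``n``     monomer separations 1 .. N//2,
      ``l``     contour separations n <b> (a),
      ``p``     contact probability,
      ``zeta``  the symmetrized variable z (1 - z/Z) for each n,
      ``slope`` local differential exponent d log p / d log zeta.
    """
    cfg = traj.config
    if cfg.topology != "ring":
        raise ValueError("contact probability is defined for ring melts")
    N = cfg.chain_length
    if b is None:
        from .calibration import mean_bond_length
        b = mean_bond_length(traj, skip=skip)
    box = cfg.box
    rc2 = (r_c * A) ** 2          # embedding units
    nmax = N // 2
    acc = np.zeros(nmax + 1)
    cnt = np.zeros(nmax + 1)
    for s in range(skip, traj.n_snapshots):
        wrapped = np.mod(traj.coords[s], np.array(box))
        for c in range(cfg.n_chains):
            p = wrapped[cfg.chains[c]]
            for n in range(1, nmax + 1):
                d = _min_image(np.roll(p, -n, axis=0) - p, box)
                hits = ((d ** 2).sum(axis=1) <= rc2)
                acc[n] += hits.mean()
                cnt[n] += 1
    n = np.arange(1, nmax + 1)
    p = acc[1:] / np.maximum(cnt[1:], 1)
    return {"n": n, "l": n * b, "p": p, "N": N}


def zeta_transform(n: np.ndarray, N: int, N_e: float):
    """Map ring contour separations onto zeta = z (1 - z/Z).

    z = n / N_e and Z = N / N_e; zeta is symmetric under z <-> Z - z, so
    both arcs of the ring collapse onto one variable.
    """
    z = np.asarray(n, dtype=float) / N_e
    Z = N / N_e
    return z * (1.0 - z / Z)


def local_slope(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Centered local differential exponent d log y / d log x."""
    lx, ly = np.log(x), np.log(y)
    return np.gradient(ly, lx)


# ---------------------------------------------------------------------------
# scaling fits
# ---------------------------------------------------------------------------

def fit_scaling(x: np.ndarray, y: np.ndarray,
                min_span_decades: float = 0.5) -> tuple[float, float]:
    """Least-squares power-law exponent of y ~ x^alpha in log-log space.

    Returns (exponent, stderr).  Requires at least 3 points spanning at
    least ``min_span_decades`` decades in x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x > 0) & (y > 0)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 positive points")
    if np.log10(x.max() / x.min()) < min_span_decades:
        raise ValueError(
            f"x range spans {np.log10(x.max() / x.min()):.2f} decades "
            f"< {min_span_decades}"
        )
    res = _stats.linregress(np.log(x), np.log(y))
    return float(res.slope), float(res.stderr)


# ---------------------------------------------------------------------------
# per-melt summary
# ---------------------------------------------------------------------------

@dataclass
class StaticSummary:
    """Ensemble structural summary of one (kappa, N) ring melt."""

    kappa_bend: float
    N: int
    rg2: float                       # <R_g^2> (a^2)
    rg2_err: float
    rm2: float                       # <R_m^2> (a^2)
    rm2_err: float
    eigenvalues: np.ndarray          # <Lambda_1..3> ascending (a^2)
    b: float
    extras: dict = field(default_factory=dict)


def static_summary(traj: Trajectory, skip: int = 0) -> StaticSummary:
    """Compute the per-snapshot-averaged static observables of a melt."""
    cfg = traj.config
    from .calibration import mean_bond_length
    b = mean_bond_length(traj, skip=skip)
    rg2, rm2, eig = [], [], []
    ring = cfg.topology == "ring"
    for s in range(skip, traj.n_snapshots):
        for c in range(cfg.n_chains):
            p = traj.coords[s][cfg.chains[c]]
            rg2.append(gyration_radius_sq(p))
            eig.append(gyration_tensor(p))
            if ring:
                rm2.append(magnetic_radius_sq(p))
    k = len(rg2)
    return StaticSummary(
        kappa_bend=cfg.kappa_bend,
        N=cfg.chain_length,
        rg2=float(np.mean(rg2)),
        rg2_err=float(np.std(rg2, ddof=1) / np.sqrt(k)) if k > 1 else 0.0,
        rm2=float(np.mean(rm2)) if rm2 else float("nan"),
        rm2_err=float(np.std(rm2, ddof=1) / np.sqrt(k)) if len(rm2) > 1 else 0.0,
        eigenvalues=np.mean(eig, axis=0),
        b=b,
    )
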