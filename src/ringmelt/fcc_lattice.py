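"""Geometry of the face-centered-cubic lattice.

The fcc lattice is embedded as the integer triples ``(x, y, z)`` with even
coordinate sum.  In this embedding the nearest-neighbor bond length is
``a = sqrt(2)`` embedding units; all physical observables are reported in
units of ``a``.  Integer arithmetic makes occupancy checks and periodic
wrapping exact, which is why the embedding (rather than a primitive-cell
basis) is used throughout.

Two consecutive non-zero ("effective") bonds of a chain enclose a discrete
angle theta.  On the fcc lattice ``cos theta`` can only take the five values
``{1, 1/2, 0, -1/2, -1}`` (bond angles 0, 60, 90, 120, 180 degrees) with
degeneracies ``Omega = {1, 4, 2, 4, 1}`` for a fixed first bond.  For an
ideal chain (no excluded volume) with bending energy
``E = -kappa_bend * sum_i cos theta_i`` over effective-bond pairs, the
stationary angle distribution is the discrete Boltzmann form

    P_ideal(kappa; cos theta) = Omega(cos theta) exp(kappa cos theta) / Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "A",
    "LatticeGeometry",
    "neighbor_vectors",
    "angle_degeneracy",
    "angle_table",
    "ideal_angle_distribution",
    "COS_VALUES",
]

#: nearest-neighbor bond length in embedding units
A: float = float(np.sqrt(2.0))

# the 12 fcc nearest-neighbor displacements: permutations of (+-1, +-1, 0),
# in a fixed deterministic order
_NEIGHBORS = np.array(
    [
        (1, 1, 0), (1, -1, 0), (-1, 1, 0), (-1, -1, 0),
        (1, 0, 1), (1, 0, -1), (-1, 0, 1), (-1, 0, -1),
        (0, 1, 1), (0, 1, -1), (0, -1, 1), (0, -1, -1),
    ],
    dtype=np.int64,
)

#: achievable values of cos(theta) between consecutive effective bonds
COS_VALUES = (1.0, 0.5, 0.0, -0.5, -1.0)


def neighbor_vectors() -> np.ndarray:
    """Return the 12 fcc nearest-neighbor displacement vectors.

    The order is deterministic; the set is closed under negation and every
    vector has squared embedding length 2 (i.e. length ``a``).
    """
    return _NEIGHBORS.copy()


def _enumerate_angle_table() -> dict[float, int]:
    """Brute-force the degeneracy table over all ordered bond pairs.

    For a fixed first bond, counts the second bonds at each value of
    cos(theta).  By lattice symmetry the table is independent of the choice
    of first bond; this is asserted.
    """
    table: dict[float, int] | None = None
    for b1 in _NEIGHBORS:
        counts: dict[float, int] = {}
        for b2 in _NEIGHBORS:
            c = float(np.dot(b1, b2)) / 2.0  # |b1||b2| = 2
            counts[c] = counts.get(c, 0) + 1
        if table is None:
            table = counts
        elif table != counts:  # pragma: no cover - lattice symmetry
            raise AssertionError("angle table depends on first bond")
    assert table is not None
    return table


_ANGLE_TABLE: dict[float, int] = _enumerate_angle_table()


def angle_table() -> dict[float, int]:
    """Degeneracy Omega(cos theta) for a fixed first bond; sums to 12."""
    return dict(_ANGLE_TABLE)


def angle_degeneracy(cos_theta: float) -> int:
    """Return Omega(cos theta), the number of lattice states of the second
    of two successive bonds at the given discrete angle.

    Raises
    ------
    ValueError
        If ``cos_theta`` is not one of the achievable lattice values.
    """
    try:
        return _ANGLE_TABLE[float(cos_theta)]
    except KeyError:
        raise ValueError(
            f"cos(theta) = {cos_theta!r} is not an fcc bond angle; "
            f"achievable values: {sorted(_ANGLE_TABLE)}"
        ) from None


def ideal_angle_distribution(kappa_bend: float) -> dict[float, float]:
    """Boltzmann angle distribution of an ideal (phantom) chain.

    Parameters
    ----------
    kappa_bend : float
        Bending stiffness in units of k_B T; must be >= 0.

    Returns
    -------
    dict mapping each achievable cos(theta) to its probability.  At
    ``kappa_bend = 0`` this is ``Omega / 12``; for large ``kappa_bend`` the
    weight concentrates on cos(theta) = 1.
    """
    if kappa_bend < 0:
        raise ValueError("kappa_bend must be non-negative")
    cos = np.array(sorted(_ANGLE_TABLE, reverse=True))
    omega = np.array([_ANGLE_TABLE[c] for c in cos], dtype=float)
    # subtract the max exponent for numerical safety at large kappa
    w = omega * np.exp(kappa_bend * (cos - cos.max()))
    w /= w.sum()
    return {float(c): float(p) for c, p in zip(cos, w)}


@dataclass(frozen=True)
class LatticeGeometry:
    """Bundle of the fcc geometric data used across the package."""

    embedding_basis: np.ndarray = field(
        default_factory=lambda: np.array(
            [(1, 1, 0), (1, 0, 1), (0, 1, 1)], dtype=np.int64
        )
    )
    neighbor_set: np.ndarray = field(default_factory=neighbor_vectors)
    lattice_unit: float = A

    @property
    def angle_table(self) -> dict[float, int]:
        return angle_table()

    @staticmethod
    def is_site(x: int, y: int, z: int) -> bool:
        """fcc sites are the integer triples with even coordinate sum."""
        return (x + y + z) % 2 == 0
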