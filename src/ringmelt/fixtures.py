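"""Deterministic toy conformations used as oracles and positive controls.

All fixtures return float coordinate arrays in embedding units (multiply
lengths in a by sqrt 2) unless stated otherwise.  They instantiate the
analytically solvable objects used throughout the test suite: a
double-folded hairpin with the closed-form bond correlation, a discretized
circle (magnetic radius R, minimal surface pi R^2), a Hopf link (linking
number +-1), an unlinked threaded pair (even piercings, zero signed flux),
a figure-eight (zero oriented area) and a straight rod.
"""

from __future__ import annotations

import numpy as np

from .fcc_lattice import A

__all__ = ["generate_fixture", "FIXTURES"]


def _circle(radius: float = 3.0, n: int = 64, z: float = 0.0) -> np.ndarray:
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.c_[radius * np.cos(th), radius * np.sin(th),
                 np.full(n, z)] * A


def _double_folded_filament(half_length: int = 20) -> np.ndarray:
    """Open filament of 2*half_length bonds folded exactly at its middle.

    Going out along +x for ``half_length`` unit bonds and back along -x;
    its bond correlation at contour separation z (in units of the half
    length) is (1 - 3z/2)/(1 - z/2) for z < 1 and -1 for 1 <= z < 2.
    """
    out = np.arange(half_length + 1)
    back = out[-2::-1]
    x = np.concatenate([out, back]).astype(float)
    return np.c_[x, np.zeros_like(x), np.zeros_like(x)] * A


def _double_folded_ring(half_length: int = 20, gap: float = 0.05) -> np.ndarray:
    """Closed, almost-flat double-folded loop (out at y=0, back at y=gap)."""
    xs = np.arange(half_length + 1, dtype=float)
    top = np.c_[xs, np.full_like(xs, gap), np.zeros_like(xs)]
    bot = np.c_[xs[::-1], np.zeros_like(xs), np.zeros_like(xs)]
    return np.vstack([bot, top]) * A


def _hopf_link() -> tuple[np.ndarray, np.ndarray]:
    """Two interlocked rectangles with |linking number| = 1."""
    a = np.array([[-2, -2, 0], [2, -2, 0], [2, 2, 0], [-2, 2, 0]], float)
    b = np.array([[0, 0, -2], [4, 0, -2], [4, 0, 2], [0, 0, 2]], float)
    return a * A, b * A


def _threaded_pair() -> tuple[np.ndarray, np.ndarray]:
    """Ring A (planar circle) threaded twice by unlinked ring B.

    B passes through A's disc and back out: two piercings of opposite
    sign, zero signed flux, linking number 0.
    """
    a = _circle(radius=3.0, n=48)
    b = np.array([[-1, 0, -2], [1, 0, -2], [1, 0, 2], [-1, 0, 2]], float) * A
    return a, b


def _figure_eight(lobe: float = 2.0, n: int = 32) -> np.ndarray:
    """Two equal lobes traversed with opposite orientation: net area 0."""
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    # right lobe traversed clockwise, left lobe counter-clockwise: the two
    # oriented areas are opposite and cancel exactly
    right = np.c_[lobe * (1 - np.cos(th)), lobe * np.sin(th), np.zeros(n)]
    left = np.c_[lobe * (np.cos(th) - 1), lobe * np.sin(th), np.zeros(n)]
    return np.vstack([right, left]) * A


def _straight_rod(n: int = 20) -> np.ndarray:
    x = np.arange(n, dtype=float)
    return np.c_[x, np.zeros(n), np.zeros(n)] * A


FIXTURES = {
    "planar_circle": _circle,
    "double_folded_filament": _double_folded_filament,
    "double_folded_ring": _double_folded_ring,
    "hopf_link": _hopf_link,
    "threaded_pair": _threaded_pair,
    "figure_eight": _figure_eight,
    "straight_rod": _straight_rod,
}


def generate_fixture(name: str, **kwargs):
    """Return the named fixture's coordinates (tuple of arrays for pairs).

    Raises KeyError for unknown names; see ``FIXTURES`` for the catalog.
    """
    try:
        fn = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return fn(**kwargs)
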