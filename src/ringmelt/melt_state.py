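"""Melt configurations: representation, construction, validation, topology.

A melt is ``M`` chains of ``N`` monomers each on the fcc lattice (see
:mod:`ringmelt.fcc_lattice`) inside a periodic box with all-even edge
lengths (so that site parity survives wrapping).  Consecutive monomers sit
on nearest-neighbor sites (an "effective" bond of length ``a``) or on the
same site (a unit of stored length, bond length 0).  At most two
*consecutive* monomers may share a site, and non-consecutive monomers never
share a site (excluded volume).

Ring melts are built unknotted and pairwise non-concatenated by
construction: each ring is laid out as a flat "racetrack" loop confined to
a single lattice plane, and distinct rings occupy disjoint slabs.  Planar
loops in disjoint regions can neither be knotted nor linked.  Stored-length
units are then distributed along each loop to reach the requested monomers
per site.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np

from .fcc_lattice import neighbor_vectors

__all__ = [
    "MeltConfiguration",
    "Trajectory",
    "ValidationReport",
    "MeltConstructionError",
    "validate",
    "build_ring_melt",
    "build_linear_melt",
    "linking_number",
    "linking_matrix",
    "unwrap",
    "wrap",
    "write_snapshot",
    "read_snapshot",
    "write_trajectory",
    "read_trajectory",
]


class MeltConstructionError(ValueError):
    """Raised when a requested melt geometry cannot be realized."""


@dataclass
class MeltConfiguration:
    """State of a melt: wrapped integer coordinates plus chain topology.

    Attributes
    ----------
    coords : (n_monomers, 3) int array of wrapped fcc sites.
    chains : (M, N) int array of monomer indices; row ``c`` lists chain
        ``c``'s monomers in order (cyclic for rings).
    box : length-3 tuple of even ints, embedding units.
    kappa_bend : bending stiffness (k_B T).
    topology : "ring" or "linear".
    pinned : set of frozen chain ids (rings only).
    """

    coords: np.ndarray
    chains: np.ndarray
    box: tuple[int, int, int]
    kappa_bend: float = 0.0
    topology: str = "ring"
    pinned: set[int] = field(default_factory=set)

    @property
    def n_chains(self) -> int:
        return self.chains.shape[0]

    @property
    def chain_length(self) -> int:
        return self.chains.shape[1]

    @property
    def n_monomers(self) -> int:
        return self.coords.shape[0]

    @property
    def n_sites(self) -> int:
        lx, ly, lz = self.box
        return lx * ly * lz // 2

    @property
    def occupancy(self) -> float:
        """Monomers per fcc site over the whole box."""
        return self.n_monomers / self.n_sites

    @property
    def monomer_density(self) -> float:
        """Monomer number density rho * a^3 (site volume is a^3 / sqrt 2)."""
        return self.occupancy * np.sqrt(2.0)

    def site_occupants(self) -> dict[tuple[int, int, int], list[int]]:
        occ: dict[tuple[int, int, int], list[int]] = {}
        for m, xyz in enumerate(self.coords):
            occ.setdefault(tuple(int(v) for v in xyz), []).append(m)
        return occ

    def copy(self) -> "MeltConfiguration":
        return MeltConfiguration(
            coords=self.coords.copy(),
            chains=self.chains.copy(),
            box=self.box,
            kappa_bend=self.kappa_bend,
            topology=self.topology,
            pinned=set(self.pinned),
        )


@dataclass
class Trajectory:
    """Time-ordered snapshots of a run, with *unwrapped* coordinates.

    Times are in units of tau_MC (one attempted move per monomer).
    Unwrapped lattice coordinates remain integers with even coordinate sum.
    """

    times: np.ndarray                      # (S,) floats, strictly increasing
    coords: np.ndarray                     # (S, n_monomers, 3) int64, unwrapped
    config: MeltConfiguration              # topology / box / kappa metadata
    seed: int | None = None
    info: dict = field(default_factory=dict)   # provenance (acceptance rate, ...)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory timestamps must strictly increase")

    @property
    def n_snapshots(self) -> int:
        return len(self.times)

    def snapshot(self, i: int) -> MeltConfiguration:
        """Wrapped configuration at snapshot ``i``."""
        cfg = self.config.copy()
        cfg.coords = wrap(self.coords[i], self.config.box)
        return cfg


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __bool__(self) -> bool:  # truthy iff valid
        return self.ok


_NEI_SET = {tuple(v) for v in neighbor_vectors()}


def _min_image(d: np.ndarray, box: tuple[int, int, int]) -> np.ndarray:
    """Minimum-image displacement for integer coordinate differences."""
    d = np.asarray(d).copy()
    for k in range(3):
        L = box[k]
        dk = d[..., k]
        dk[dk > L // 2] -= L
        dk[dk < -(L // 2)] += L
    return d


def validate(config: MeltConfiguration) -> ValidationReport:
    """Report every violated melt invariant (empty report iff valid)."""
    rep = ValidationReport()
    lx, ly, lz = config.box
    if lx % 2 or ly % 2 or lz % 2:
        rep.errors.append(f"box dimensions must all be even, got {config.box}")
    if np.any((config.coords.sum(axis=1)) % 2 != 0):
        bad = np.nonzero(config.coords.sum(axis=1) % 2)[0][:5]
        rep.errors.append(f"monomers on odd-parity sites (not fcc): {bad.tolist()}")
    if np.any(config.coords < 0) or np.any(config.coords >= np.array(config.box)):
        rep.errors.append("coordinates not wrapped into the box")

    n_chains, n = config.chains.shape
    ring = config.topology == "ring"
    # bond-length / stored-length constraints along each chain
    for c in range(n_chains):
        idx = config.chains[c]
        pos = config.coords[idx]
        nb = n if ring else n - 1
        prev_zero = False
        for j in range(nb):
            d = _min_image(pos[(j + 1) % n] - pos[j], config.box)
            t = tuple(int(v) for v in d)
            zero = t == (0, 0, 0)
            if not zero and t not in _NEI_SET:
                rep.errors.append(
                    f"chain {c}: bond {j} has invalid displacement {t}"
                )
            if zero and prev_zero:
                rep.errors.append(
                    f"chain {c}: three consecutive monomers share a site at bond {j}"
                )
            prev_zero = zero

    # excluded volume: a site holds at most 2 monomers, and then only a
    # consecutive pair of the same chain
    chain_of = np.empty(config.n_monomers, dtype=np.int64)
    rank_of = np.empty(config.n_monomers, dtype=np.int64)
    for c in range(n_chains):
        chain_of[config.chains[c]] = c
        rank_of[config.chains[c]] = np.arange(n)
    for site, occupants in config.site_occupants().items():
        if len(occupants) > 2:
            rep.errors.append(f"site {site} holds {len(occupants)} monomers")
        elif len(occupants) == 2:
            m1, m2 = occupants
            same_chain = chain_of[m1] == chain_of[m2]
            dr = abs(int(rank_of[m1]) - int(rank_of[m2]))
            consecutive = same_chain and (dr == 1 or (ring and dr == n - 1))
            if not consecutive:
                rep.errors.append(
                    f"site {site}: non-consecutive monomers {m1},{m2} share it"
                )
    return rep


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _racetrack_sites(m: int, x0: int, y0: int, z: int) -> list[tuple[int, int, int]]:
    """Closed loop of 2m+2 fcc sites in plane ``z``.

    Two zigzag legs along x (rows y0/y0+1 out, y0+2/y0+3 back) joined by one
    turn column on each side.  Footprint: x in [x0-1, x0+m], 4 rows of y.
    """
    def ylow(x: int, base: int) -> int:
        # site parity: x + y + z even
        return base if (x + base + z) % 2 == 0 else base + 1

    sites = [(x, ylow(x, y0), z) for x in range(x0, x0 + m)]          # leg out
    xt = x0 + m
    sites.append((xt, ylow(xt, y0 + 1), z))                           # right turn
    sites += [(x, ylow(x, y0 + 2), z) for x in range(x0 + m - 1, x0 - 1, -1)]
    xt = x0 - 1
    sites.append((xt, ylow(xt, y0 + 1), z))                           # left turn
    return sites


def _divisor_pairs(m: int) -> list[tuple[int, int]]:
    return [(d, m // d) for d in range(1, m + 1) if m % d == 0]


def _ceil_even(v: int) -> int:
    return v if v % 2 == 0 else v + 1


def _build_melt(
    M: int,
    N: int,
    occupancy: float,
    kappa_bend: float,
    seed: int,
    topology: str,
) -> MeltConfiguration:
    if N < 3:
        raise MeltConstructionError("need N >= 3 monomers per chain")
    if not 0 < occupancy <= 2:
        raise MeltConstructionError("occupancy must be in (0, 2]")

    # sites covered per chain: c = 2m+2 on a footprint of 2m+4 sites
    target_sites = N / occupancy
    best = None
    for m in range(2, max(3, N)):
        c = 2 * m + 2
        if c > N:
            break
        if N - c > c:      # stored length cannot exceed covered sites
            continue
        lx_min = _ceil_even(m + 2)
        for gy, gz in _divisor_pairs(M):
            ly = 4 * gy
            lz = _ceil_even(gz)
            # pad x to tune the global occupancy toward the request
            for lx in range(lx_min, lx_min + 33, 2):
                sites = lx * ly * lz // 2
                occ = M * N / sites
                err = abs(occ - occupancy) / occupancy
                aspect = max(lx, ly, lz) / min(lx, ly, lz)
                # prefer an initial covered length near 0.6 N: starting on
                # the slack-rich side leaves free volume everywhere, so the
                # melt relaxes from the mobile side instead of jamming
                key = (round(err, 9), abs(c - 0.6 * N),
                       aspect, lx, ly, lz)
                if best is None or key < best[0]:
                    best = (key, m, gy, gz, lx, ly, lz)
    if best is None:
        raise MeltConstructionError(
            f"no feasible racetrack layout for M={M}, N={N}, occupancy={occupancy}"
        )
    (err, *_), m, gy, gz, lx, ly, lz = best[0], *best[1:]
    if err > 0.02:
        warnings.warn(
            f"requested occupancy {occupancy:.4g} not reachable within 2% "
            f"(even-box site counts are multiples of 4); using "
            f"{M * N / (lx * ly * lz // 2):.4g}",
            stacklevel=3,
        )

    rng = np.random.default_rng(seed)
    c_sites = 2 * m + 2
    n_stored = N - c_sites
    coords = np.empty((M * N, 3), dtype=np.int64)
    chains = np.arange(M * N, dtype=np.int64).reshape(M, N)
    chain = 0
    for gzi in range(gz):
        for gyi in range(gy):
            if chain >= M:
                break
            sites = _racetrack_sites(m, x0=1, y0=4 * gyi, z=gzi)
            # double n_stored evenly spaced sites; rotate start per chain
            offset = int(rng.integers(c_sites))
            doubled = set()
            if n_stored:
                step = c_sites / n_stored
                doubled = {int((offset + round(k * step)) % c_sites)
                           for k in range(n_stored)}
                while len(doubled) < n_stored:   # collisions from rounding
                    doubled.add(int(rng.integers(c_sites)))
            mono = []
            for j, s in enumerate(sites):
                mono.append(s)
                if j in doubled:
                    mono.append(s)
            assert len(mono) == N
            coords[chains[chain]] = np.array(mono, dtype=np.int64)
            chain += 1
    box = (lx, ly, lz)
    cfg = MeltConfiguration(
        coords=wrap(coords, box),
        chains=chains,
        box=box,
        kappa_bend=kappa_bend,
        topology=topology,
    )
    rep = validate(cfg)
    if not rep.ok:  # pragma: no cover - construction guarantee
        raise MeltConstructionError("builder produced invalid melt: " + rep.errors[0])
    return cfg


def build_ring_melt(
    M: int, N: int, occupancy: float, kappa_bend: float = 0.0, seed: int = 0
) -> MeltConfiguration:
    """Build a valid ring melt; rings unknotted and pairwise unlinked.

    ``occupancy`` is monomers per fcc site; the melt-condition value
    matching rho a^3 = 1.77 is 1.25 (= 1.77 / sqrt 2).  The realized
    occupancy is the closest achievable with an all-even box (warning if
    further than 2% from the request).
    """
    return _build_melt(M, N, occupancy, kappa_bend, seed, "ring")


def build_linear_melt(
    M: int, N: int, occupancy: float, kappa_bend: float = 0.0, seed: int = 0
) -> MeltConfiguration:
    """Build a melt of open linear chains (same layout, loop not closed)."""
    return _build_melt(M, N, occupancy, kappa_bend, seed, "linear")


# ---------------------------------------------------------------------------
# unwrap / wrap
# ---------------------------------------------------------------------------

def wrap(coords: np.ndarray, box: tuple[int, int, int]) -> np.ndarray:
    """Wrap (possibly unwrapped) integer coordinates into the box."""
    return np.mod(coords, np.array(box, dtype=np.int64))


def unwrap(config: MeltConfiguration) -> np.ndarray:
    """Per-chain continuous coordinates: bond displacements of length 0 or a.

    The first monomer of each chain anchors at its wrapped position; each
    subsequent monomer is placed at the previous one plus the minimum-image
    bond displacement.  For rings, the closure displacement must be exactly
    zero (error otherwise).
    """
    out = np.empty_like(config.coords)
    ring = config.topology == "ring"
    for c in range(config.n_chains):
        idx = config.chains[c]
        pos = config.coords[idx].astype(np.int64)
        up = np.empty_like(pos)
        up[0] = pos[0]
        steps = _min_image(np.diff(pos, axis=0), config.box)
        ok = np.all((np.abs(steps) <= 1), axis=1) & (
            np.isin((steps ** 2).sum(axis=1), (0, 2))
        )
        if not np.all(ok):
            raise ValueError(f"chain {c} is broken (invalid bond)")
        up[1:] = pos[0] + np.cumsum(steps, axis=0)
        if ring:
            closure = _min_image(pos[0] - pos[-1], config.box)
            if np.any(up[-1] + closure != up[0]):
                raise ValueError(f"ring {c} does not close in unwrapped space")
        out[idx] = up
    return out


# ---------------------------------------------------------------------------
# Gauss linking number
# ---------------------------------------------------------------------------

def _segments(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-polygon segment start/end points, zero-length edges dropped."""
    a = np.asarray(coords, dtype=float)
    b = np.roll(a, -1, axis=0)
    keep = np.any(a != b, axis=1)
    return a[keep], b[keep]


def linking_number(ring_a: np.ndarray, ring_b: np.ndarray) -> int:
    """Gauss linking number of two closed polygonal curves.

    Uses the analytic solid-angle formula for segment pairs (the Gauss
    double integral evaluated exactly on polygons); the sum over pairs is
    4*pi times an integer for disjoint closed curves.

    Parameters are unwrapped coordinate arrays; curves must be closed
    polygons (consecutive duplicate points are tolerated).
    """
    a1, a2 = _segments(ring_a)
    b1, b2 = _segments(ring_b)
    if len(a1) < 3 or len(b1) < 3:
        raise ValueError("linking number requires two closed curves")
    total = 0.0
    for i in range(len(a1)):
        total += _solid_angles(a1[i], a2[i], b1, b2).sum()
    lk = total / (4.0 * np.pi)
    lk_int = int(np.rint(lk))
    if abs(lk - lk_int) > 1e-6:
        raise ValueError(
            f"Gauss sum {lk} is not an integer; curves may touch or be open"
        )
    return lk_int


def _solid_angles(p1: np.ndarray, p2: np.ndarray,
                  q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Signed solid angle of the quadrilateral (Gauss map) for one segment
    of curve A against every segment of curve B (vectorized over B)."""
    r = [q1 - p1, q2 - p1, q2 - p2, q1 - p2]
    n = []
    for k in range(4):
        v = np.cross(r[k], r[(k + 1) % 4])
        norm = np.linalg.norm(v, axis=-1, keepdims=True)
        norm[norm == 0] = 1.0
        n.append(v / norm)
    ang = np.zeros(len(q1))
    for k in range(4):
        d = np.clip((n[k] * n[(k + 1) % 4]).sum(axis=-1), -1.0, 1.0)
        ang += np.arcsin(d)
    sign = np.sign((np.cross(q2 - q1, p2 - p1) * (p1 - q1)).sum(axis=-1))
    return ang * sign


def linking_matrix(config: MeltConfiguration, warn_extent: bool = True) -> np.ndarray:
    """Pairwise Gauss linking numbers, each partner taken in the periodic
    image nearest (by center of mass) to the reference ring.

    Linking across the torus is ill-defined; a warning is emitted when a
    ring's spatial extent exceeds half the box, where the nearest-image
    convention becomes questionable.
    """
    if config.topology != "ring":
        raise ValueError("linking matrix is defined for ring melts")
    up = unwrap(config)
    M = config.n_chains
    box = np.array(config.box, dtype=float)
    rings = [up[config.chains[c]].astype(float) for c in range(M)]
    if warn_extent:
        for c, r in enumerate(rings):
            ext = r.max(axis=0) - r.min(axis=0)
            if np.any(ext > box / 2):
                warnings.warn(
                    f"ring {c} extent {ext} exceeds half the box; "
                    "nearest-image linking may be ambiguous",
                    stacklevel=2,
                )
                break
    lk = np.zeros((M, M), dtype=np.int64)
    coms = [r.mean(axis=0) for r in rings]
    for i in range(M):
        for j in range(i + 1, M):
            shift = np.rint((coms[j] - coms[i]) / box) * box
            lk[i, j] = lk[j, i] = linking_number(rings[i], rings[j] - shift)
    return lk


# ---------------------------------------------------------------------------
# snapshot / trajectory text format
# ---------------------------------------------------------------------------

_MAGIC = "#RINGMELT 1"


def write_snapshot(config: MeltConfiguration, fh: io.TextIOBase,
                   coords: np.ndarray | None = None) -> None:
    """Write one snapshot in the structured-text format (bit-exact I/O)."""
    c = config.coords if coords is None else coords
    fh.write(_MAGIC + "\n")
    fh.write("box %d %d %d\n" % config.box)
    fh.write("kappa %r\n" % float(config.kappa_bend))
    fh.write("topology %s\n" % config.topology)
    fh.write("chains %d\n" % config.n_chains)
    for ci in range(config.n_chains):
        idx = config.chains[ci]
        fh.write("chain %d %d\n" % (ci, len(idx)))
        for xyz in c[idx]:
            fh.write("%d %d %d\n" % tuple(int(v) for v in xyz))


def read_snapshot(fh: io.TextIOBase) -> MeltConfiguration | None:
    """Read one snapshot; returns None at end of stream."""
    line = fh.readline()
    while line and not line.strip():
        line = fh.readline()
    if not line:
        return None
    if line.strip() != _MAGIC:
        raise ValueError(f"bad snapshot header: {line!r}")
    box = tuple(int(v) for v in fh.readline().split()[1:4])
    kappa = float(fh.readline().split()[1])
    topology = fh.readline().split()[1]
    m = int(fh.readline().split()[1])
    chains = []
    coords = []
    for _ in range(m):
        _, cid, n = fh.readline().split()
        n = int(n)
        start = len(coords)
        for _ in range(n):
            coords.append([int(v) for v in fh.readline().split()])
        chains.append(list(range(start, start + n)))
    return MeltConfiguration(
        coords=np.array(coords, dtype=np.int64),
        chains=np.array(chains, dtype=np.int64),
        box=box,  # type: ignore[arg-type]
        kappa_bend=kappa,
        topology=topology,
    )


def write_trajectory(traj: Trajectory, fh: io.TextIOBase) -> None:
    """Concatenated snapshots, each preceded by a ``time`` record.

    Trajectory snapshots carry *unwrapped* integer coordinates (needed for
    displacement observables); ``read_trajectory`` round-trips bit-exactly.
    """
    for i, t in enumerate(traj.times):
        fh.write("time %r\n" % float(t))
        write_snapshot(traj.config, fh, coords=traj.coords[i])


def read_trajectory(fh: io.TextIOBase) -> Trajectory:
    times = []
    frames = []
    config = None
    while True:
        line = fh.readline()
        while line and not line.strip():
            line = fh.readline()
        if not line:
            break
        if not line.startswith("time "):
            raise ValueError(f"expected 'time' record, got {line!r}")
        times.append(float(line.split()[1]))
        snap = read_snapshot(fh)
        if snap is None:
            raise ValueError("truncated trajectory")
        if config is None:
            config = snap
        frames.append(snap.coords)
    if config is None:
        raise ValueError("empty trajectory stream")
    config.coords = wrap(config.coords, config.box)
    return Trajectory(
        times=np.array(times), coords=np.array(frames), config=config
    )
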