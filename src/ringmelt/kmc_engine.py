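"""Metropolis kinetic Monte Carlo dynamics for stored-length lattice melts.

One elementary attempt: pick a monomer uniformly at random, pick one of the
12 fcc nearest-neighbor displacements uniformly, and accept the move iff

1. connectivity - both bonds adjacent to the monomer keep length 0 or a;
2. excluded volume - the destination site is empty or holds exactly one
   monomer, which must be a chain neighbor of the mover (this also enforces
   "at most two consecutive monomers per site");
3. a Metropolis test on the bending-energy change.  The bending energy is
   ``E = -kappa_bend * sum_i cos(theta_i)`` with one term per monomer,
   where ``theta_i`` is the angle between the nearest *effective*
   (non-zero) bonds on the two sides of monomer i - zero-length bonds are
   skipped, so both monomers of a stored-length pair see the same flanking
   bond pair.  This per-monomer convention keeps the number of energy
   terms fixed at N, which makes stored length energetically neutral in
   straight chain sections and lets the equilibrium slack *grow* with
   stiffness, as observed in the reference calibration.

A monomer moving onto a chain neighbor's site creates a unit of stored
length; a stored-length unit hopping along the chain realizes
reptation-like mass transport, while ordinary hops are Rouse-like moves.
One kMC time unit tau_MC equals one attempted move per monomer (N*M
attempts).

The inner loop is compiled with numba; the compiled stream is seeded once
per run so that a run is fully reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .fcc_lattice import neighbor_vectors
from .melt_state import MeltConfiguration, Trajectory, validate

__all__ = [
    "SimulationParams",
    "MoveOutcome",
    "REASONS",
    "attempt_move",
    "run",
    "pin_rings",
]

#: rejection-reason codes used by the compiled kernel
REASONS = {0: "accepted", 1: "pinned", 2: "connectivity",
           3: "excluded volume", 4: "metropolis"}


@dataclass
class SimulationParams:
    """Run-control parameters.

    sweeps : total simulated time in tau_MC units (one sweep = one
        attempted move per monomer).
    snapshot_every : record every this-many sweeps (linear schedule); when
        ``log_snapshots`` is true, snapshots follow a logarithmic grid with
        ``points_per_decade`` points starting at 1 tau_MC instead.
    pin_fraction : fraction of rings to freeze before the run (0 disables).
    seed : master seed of the run's single RNG stream.
    """

    sweeps: int = 1000
    snapshot_every: int = 0
    log_snapshots: bool = False
    points_per_decade: int = 8
    pin_fraction: float = 0.0
    seed: int = 0
    excluded_volume: bool = True   # test hook: False simulates phantom chains

    def __post_init__(self) -> None:
        if self.sweeps < 0:
            raise ValueError("sweeps must be >= 0")
        if not 0.0 <= self.pin_fraction <= 1.0:
            raise ValueError("pin_fraction must be in [0, 1]")

    def schedule(self) -> np.ndarray:
        """Snapshot times in sweeps (excluding t=0), sorted, unique."""
        if self.sweeps == 0:
            return np.array([], dtype=np.int64)
        if self.log_snapshots:
            n = int(np.ceil(np.log10(max(self.sweeps, 2))
                            * self.points_per_decade))
            t = np.unique(np.rint(
                10 ** np.linspace(0, np.log10(self.sweeps), n + 1)
            ).astype(np.int64))
            return t[t >= 1]
        every = self.snapshot_every or self.sweeps
        return np.arange(every, self.sweeps + 1, every, dtype=np.int64)


@dataclass
class MoveOutcome:
    monomer: int
    displacement: np.ndarray
    accepted: bool
    reason: str = "accepted"


# ---------------------------------------------------------------------------
# compiled kernel
# ---------------------------------------------------------------------------

_NEI = neighbor_vectors()


@njit(cache=True)
def _seed_stream(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _bond(pos_w, box, a, b):
    """Minimum-image bond vector from monomer a to monomer b (|d| <= 1)."""
    d0 = pos_w[b, 0] - pos_w[a, 0]
    d1 = pos_w[b, 1] - pos_w[a, 1]
    d2 = pos_w[b, 2] - pos_w[a, 2]
    if d0 > box[0] // 2:
        d0 -= box[0]
    elif d0 < -(box[0] // 2):
        d0 += box[0]
    if d1 > box[1] // 2:
        d1 -= box[1]
    elif d1 < -(box[1] // 2):
        d1 += box[1]
    if d2 > box[2] // 2:
        d2 -= box[2]
    elif d2 < -(box[2] // 2):
        d2 += box[2]
    return d0, d1, d2


@njit(cache=True)
def _monomer_cos(pos_w, box, N, is_ring, c0, q):
    """cos(theta) of the bending angle at monomer rank ``q``: the angle
    between the nearest effective (non-zero) bond before and after the
    monomer.  Zero-length bonds are skipped (the energy is restricted to
    effective bonds), so both monomers of a stored-length pair see the same
    flanking bond pair.  Returns 2.0 when no angle is defined (chain end).

    Zero bonds are isolated (at most two consecutive monomers per site),
    hence the nearest effective bond is at distance one or two.
    """
    # incoming effective bond: q-1, else q-2
    j = q - 1
    if is_ring:
        j = j % N
    elif j < 0:
        return 2.0
    bi = _bond(pos_w, box, c0 + j, c0 + (j + 1) % N)
    if bi[0] == 0 and bi[1] == 0 and bi[2] == 0:
        j = j - 1
        if is_ring:
            j = j % N
        elif j < 0:
            return 2.0
        bi = _bond(pos_w, box, c0 + j, c0 + (j + 1) % N)
    # outgoing effective bond: q, else q+1
    k = q
    if not is_ring and k > N - 2:
        return 2.0
    bo = _bond(pos_w, box, c0 + k, c0 + (k + 1) % N)
    if bo[0] == 0 and bo[1] == 0 and bo[2] == 0:
        k = k + 1
        if is_ring:
            k = k % N
        elif k > N - 2:
            return 2.0
        bo = _bond(pos_w, box, c0 + k, c0 + (k + 1) % N)
    if j == k:
        return 2.0
    return 0.5 * (bi[0] * bo[0] + bi[1] * bo[1] + bi[2] * bo[2])


@njit(cache=True)
def _local_cos_sum(pos_w, box, N, is_ring, c0, r):
    """Sum of per-monomer bending cosines over monomers [r-2, r+2].

    The move of monomer r changes bonds r-1 and r only; a monomer's angle
    involves bonds q-2 .. q+1, so every angle term affected by the move
    (including terms whose flanking-bond identity changes because a bond
    switches between zero and non-zero length) belongs to a monomer in
    this window.  The difference of this sum across a move therefore
    equals the change of the full-chain bending energy.
    """
    total = 0.0
    seen = np.empty(5, dtype=np.int64)
    nseen = 0
    for off in range(-2, 3):
        q = r + off
        if is_ring:
            q = q % N
        elif q < 0 or q >= N:
            continue
        dup = False
        for t in range(nseen):
            if seen[t] == q:
                dup = True
                break
        if dup:
            continue
        seen[nseen] = q
        nseen += 1
        cq = _monomer_cos(pos_w, box, N, is_ring, c0, q)
        if cq < 1.5:
            total += cq
    return total


#: statistical weight of a stored-length unit relative to one effective-bond
#: orientation.  The configuration measure is uniform over valid states
#: (weight 1 per stored unit), modulated only by the bending Boltzmann
#: factor; the weight is kept explicit so phantom-chain statistics can be
#: cross-checked against transfer-matrix results.
STORED_LENGTH_WEIGHT = 1.0
_LOG_OMEGA = float(np.log(STORED_LENGTH_WEIGHT))


@njit(cache=True)
def _try_move(pos_w, pos_u, box, occ_cnt, occ_id, pinned, nei,
              kappa, log_omega, ev_on, is_ring, N, m, direction):
    """Attempt one move of monomer m along ``nei[direction]``.

    Returns a reason code (0 accepted); state arrays are updated in place
    on acceptance.
    """
    c = m // N
    if pinned[c]:
        return 1
    r = m % N
    c0 = c * N
    vx = nei[direction, 0]
    vy = nei[direction, 1]
    vz = nei[direction, 2]
    nx = (pos_w[m, 0] + vx) % box[0]
    ny = (pos_w[m, 1] + vy) % box[1]
    nz = (pos_w[m, 2] + vz) % box[2]

    # connectivity: both adjacent bonds must stay of length 0 or a
    has_prev = is_ring or r > 0
    has_next = is_ring or r < N - 1
    prev = c0 + (r - 1) % N
    nxt = c0 + (r + 1) % N
    z_prev = False
    z_next = False
    if has_prev:
        d0 = nx - pos_w[prev, 0]
        d1 = ny - pos_w[prev, 1]
        d2 = nz - pos_w[prev, 2]
        if d0 > box[0] // 2:
            d0 -= box[0]
        elif d0 < -(box[0] // 2):
            d0 += box[0]
        if d1 > box[1] // 2:
            d1 -= box[1]
        elif d1 < -(box[1] // 2):
            d1 += box[1]
        if d2 > box[2] // 2:
            d2 -= box[2]
        elif d2 < -(box[2] // 2):
            d2 += box[2]
        dd = d0 * d0 + d1 * d1 + d2 * d2
        if dd != 0 and dd != 2:
            return 2
        z_prev = dd == 0
    if has_next:
        d0 = nx - pos_w[nxt, 0]
        d1 = ny - pos_w[nxt, 1]
        d2 = nz - pos_w[nxt, 2]
        if d0 > box[0] // 2:
            d0 -= box[0]
        elif d0 < -(box[0] // 2):
            d0 += box[0]
        if d1 > box[1] // 2:
            d1 -= box[1]
        elif d1 < -(box[1] // 2):
            d1 += box[1]
        if d2 > box[2] // 2:
            d2 -= box[2]
        elif d2 < -(box[2] // 2):
            d2 += box[2]
        dd = d0 * d0 + d1 * d1 + d2 * d2
        if dd != 0 and dd != 2:
            return 2
        z_next = dd == 0

    if ev_on:
        cnt = occ_cnt[nx, ny, nz]
        if cnt >= 2:
            return 3
        if cnt == 1:
            occupant = occ_id[nx, ny, nz, 0]
            if occupant != prev and occupant != nxt:
                return 3
            if occupant == prev and not has_prev:
                return 3
            if occupant == nxt and not has_next:
                return 3
    else:
        # phantom chains keep only the stored-length rule: never three
        # consecutive monomers on one site
        if z_prev and z_next:
            return 3
        if z_prev and has_prev:
            p2 = c0 + (r - 2) % N if (is_ring or r >= 2) else -1
            if p2 >= 0 and pos_w[p2, 0] == pos_w[prev, 0] \
                    and pos_w[p2, 1] == pos_w[prev, 1] \
                    and pos_w[p2, 2] == pos_w[prev, 2]:
                return 3
        if z_next and has_next:
            n2 = c0 + (r + 2) % N if (is_ring or r <= N - 3) else -1
            if n2 >= 0 and pos_w[n2, 0] == pos_w[nxt, 0] \
                    and pos_w[n2, 1] == pos_w[nxt, 1] \
                    and pos_w[n2, 2] == pos_w[nxt, 2]:
                return 3

    # stored-length entropy: zero bonds adjacent to m before and after the
    # move (the move can only create/destroy stored length at these bonds)
    zb = 0
    if has_prev and pos_w[m, 0] == pos_w[prev, 0] \
            and pos_w[m, 1] == pos_w[prev, 1] \
            and pos_w[m, 2] == pos_w[prev, 2]:
        zb += 1
    if has_next and pos_w[m, 0] == pos_w[nxt, 0] \
            and pos_w[m, 1] == pos_w[nxt, 1] \
            and pos_w[m, 2] == pos_w[nxt, 2]:
        zb += 1
    za = (1 if z_prev else 0) + (1 if z_next else 0)
    de = -log_omega * (za - zb)

    ox, oy, oz = pos_w[m, 0], pos_w[m, 1], pos_w[m, 2]
    if kappa != 0.0:
        e_old = -kappa * _local_cos_sum(pos_w, box, N, is_ring, c0, r)
        pos_w[m, 0], pos_w[m, 1], pos_w[m, 2] = nx, ny, nz
        e_new = -kappa * _local_cos_sum(pos_w, box, N, is_ring, c0, r)
        de += e_new - e_old
    else:
        pos_w[m, 0], pos_w[m, 1], pos_w[m, 2] = nx, ny, nz
    if de > 0.0 and np.random.random() >= np.exp(-de):
        pos_w[m, 0], pos_w[m, 1], pos_w[m, 2] = ox, oy, oz
        return 4

    # accepted: update occupancy and unwrapped position
    if ev_on:
        if occ_id[ox, oy, oz, 0] == m:
            occ_id[ox, oy, oz, 0] = occ_id[ox, oy, oz, 1]
        occ_cnt[ox, oy, oz] -= 1
        occ_id[nx, ny, nz, occ_cnt[nx, ny, nz]] = m
        occ_cnt[nx, ny, nz] += 1
    pos_u[m, 0] += vx
    pos_u[m, 1] += vy
    pos_u[m, 2] += vz
    return 0


@njit(cache=True)
def _run_chunk(pos_w, pos_u, box, occ_cnt, occ_id, pinned, nei,
               kappa, log_omega, ev_on, is_ring, N, n_attempts):
    """Run ``n_attempts`` elementary attempts; returns per-reason counts."""
    counts = np.zeros(5, dtype=np.int64)
    n = pos_w.shape[0]
    for _ in range(n_attempts):
        m = np.random.randint(0, n)
        d = np.random.randint(0, 12)
        reason = _try_move(pos_w, pos_u, box, occ_cnt, occ_id, pinned, nei,
                           kappa, log_omega, ev_on, is_ring, N, m, d)
        counts[reason] += 1
    return counts


# ---------------------------------------------------------------------------
# python driver
# ---------------------------------------------------------------------------

class _EngineState:
    """Mutable simulation state backing the compiled kernel."""

    def __init__(self, config: MeltConfiguration, excluded_volume: bool = True):
        rep = validate(config)
        if excluded_volume and not rep.ok:
            raise ValueError("invalid initial configuration: " + rep.errors[0])
        # kernel assumes chain c owns monomers [c*N, (c+1)*N); remap
        order = config.chains.ravel()
        self.order = order
        self.config = config
        self.N = config.chain_length
        self.M = config.n_chains
        self.box = np.array(config.box, dtype=np.int64)
        self.pos_w = np.ascontiguousarray(config.coords[order], dtype=np.int64)
        # per-chain continuous coordinates: bond displacements stay 0 or a
        # across periodic boundaries, so trajectory snapshots are genuinely
        # unwrapped (ring closure displacement exactly zero)
        from .melt_state import unwrap
        self.pos_u = np.ascontiguousarray(unwrap(config)[order], dtype=np.int64)
        self.is_ring = config.topology == "ring"
        self.kappa = float(config.kappa_bend)
        self.ev_on = excluded_volume
        self.pinned = np.zeros(self.M, dtype=np.bool_)
        for c in config.pinned:
            self.pinned[c] = True
        if excluded_volume:
            lx, ly, lz = config.box
            self.occ_cnt = np.zeros((lx, ly, lz), dtype=np.int8)
            self.occ_id = np.full((lx, ly, lz, 2), -1, dtype=np.int64)
            for m, (x, y, z) in enumerate(self.pos_w):
                self.occ_id[x, y, z, self.occ_cnt[x, y, z]] = m
                self.occ_cnt[x, y, z] += 1
        else:
            # phantom chains never consult the occupancy grid
            self.occ_cnt = np.zeros((1, 1, 1), dtype=np.int8)
            self.occ_id = np.full((1, 1, 1, 2), -1, dtype=np.int64)

    def unwrapped(self) -> np.ndarray:
        """Unwrapped coordinates in the original monomer indexing."""
        out = np.empty_like(self.pos_u)
        out[self.order] = self.pos_u
        return out

    def as_config(self) -> MeltConfiguration:
        cfg = self.config.copy()
        cfg.coords[self.order] = np.mod(self.pos_w, self.box)
        cfg.pinned = {int(c) for c in np.nonzero(self.pinned)[0]}
        return cfg


def pin_rings(config: MeltConfiguration, f_p: float,
              rng: np.random.Generator | int | None = None) -> MeltConfiguration:
    """Mark a uniformly random floor(f_p * M) rings as pinned (frozen).

    Returns a copy of the configuration with its ``pinned`` set replaced.
    """
    if config.topology != "ring":
        raise ValueError("pinning is defined for ring melts")
    if not 0.0 <= f_p <= 1.0:
        raise ValueError("f_p must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    k = int(np.floor(f_p * config.n_chains))
    out = config.copy()
    out.pinned = {int(c)
                  for c in rng.choice(config.n_chains, size=k, replace=False)}
    return out


def attempt_move(config: MeltConfiguration,
                 rng: np.random.Generator | int | None = None,
                 excluded_volume: bool = True) -> tuple[MoveOutcome, MeltConfiguration]:
    """Attempt a single elementary move; returns the outcome and the
    (possibly updated) configuration.

    This is the one-step reference entry point; long runs use :func:`run`.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    state = _EngineState(config, excluded_volume=excluded_volume)
    m_k = int(rng.integers(state.pos_w.shape[0]))
    d = int(rng.integers(12))
    _seed_stream(int(rng.integers(2 ** 31)))  # stream for the Metropolis draw
    reason = _try_move(state.pos_w, state.pos_u, state.box, state.occ_cnt,
                       state.occ_id, state.pinned, _NEI, state.kappa,
                       _LOG_OMEGA, state.ev_on, state.is_ring, state.N, m_k, d)
    outcome = MoveOutcome(
        monomer=int(state.order[m_k]),
        displacement=_NEI[d].copy(),
        accepted=reason == 0,
        reason=REASONS[reason],
    )
    return outcome, state.as_config()


def run(config: MeltConfiguration, params: SimulationParams,
        initial_time: float = 0.0) -> Trajectory:
    """Evolve a melt for ``params.sweeps`` tau_MC units.

    Records unwrapped snapshots on the parameter schedule (the initial
    configuration is always snapshot 0).  Fully reproducible from
    ``params.seed``; chain/monomer counts, box, and (for valid dynamics)
    the ring linking matrix are conserved.
    """
    cfg = config
    if params.pin_fraction > 0 and not cfg.pinned:
        cfg = pin_rings(cfg, params.pin_fraction,
                        np.random.SeedSequence([params.seed, 0xB1B]).generate_state(1)[0])
    state = _EngineState(cfg, excluded_volume=params.excluded_volume)
    kernel_seed = int(
        np.random.SeedSequence([params.seed, 0x5EED]).generate_state(1)[0] % (2 ** 31)
    )
    _seed_stream(kernel_seed)

    n = state.pos_w.shape[0]
    times = [initial_time]
    frames = [state.unwrapped()]
    counts = np.zeros(5, dtype=np.int64)
    prev = 0
    for t in params.schedule():
        attempts = int((t - prev) * n)
        counts += _run_chunk(state.pos_w, state.pos_u, state.box,
                             state.occ_cnt, state.occ_id, state.pinned, _NEI,
                             state.kappa, _LOG_OMEGA, state.ev_on,
                             state.is_ring, state.N, attempts)
        prev = int(t)
        times.append(initial_time + float(t))
        frames.append(state.unwrapped())
    if prev < params.sweeps:   # tail without snapshot
        counts += _run_chunk(state.pos_w, state.pos_u, state.box,
                             state.occ_cnt, state.occ_id, state.pinned, _NEI,
                             state.kappa, _LOG_OMEGA, state.ev_on,
                             state.is_ring, state.N,
                             int((params.sweeps - prev) * n))

    final = state.as_config()
    rep = validate(final) if params.excluded_volume else None
    if rep is not None and not rep.ok:  # pragma: no cover - dynamics guarantee
        raise RuntimeError("kMC run produced invalid state: " + rep.errors[0])
    attempts_total = int(counts.sum())
    info = {
        "acceptance_rate": counts[0] / attempts_total if attempts_total else 0.0,
        "rejections": {REASONS[i]: int(counts[i]) for i in range(1, 5)},
        "final_config": final,
        "kernel_seed": kernel_seed,
    }
    return Trajectory(times=np.array(times, dtype=float),
                      coords=np.array(frames), config=cfg.copy(),
                      seed=params.seed, info=info)
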