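"""Threading statistics of ring melts built on minimal-surface piercings.

A ring B that pierces the minimal surface of ring A is split by the
crossings into alternating arcs on the two sides of the surface.  Each
arc between consecutive crossings is a *threading segment* of contour
length L_t; segments shorter than the entanglement length L_e are
*shallow* threadings.  The separation length L_sep is the total contour
on the minority side, and

    Q = L_sep / (L - L_sep)          (Q = 1: the ring is half split).

Deep threadings (L_t > L_e) define the threading network: rings are
nodes, and an undirected edge joins two rings when either pierces the
other's surface with at least one deep segment.  The largest-component
fraction diagnoses how close the network is to percolating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .minimal_surface import Piercing

__all__ = [
    "ThreadingSegment",
    "ThreadingRecord",
    "ThreadingStatistics",
    "threading_segments",
    "threading_statistics",
    "build_threading_graph",
]

log = logging.getLogger(__name__)


@dataclass
class ThreadingSegment:
    """One arc of the threader between consecutive surface crossings."""

    length: float                   # contour length L_t (a)
    side: int                       # +1 / -1: side of the surface
    start: Piercing
    end: Piercing

    @property
    def d(self) -> float:
        """Euclidean distance between the two piercing-bond midpoints (a)."""
        from .fcc_lattice import A
        return float(np.linalg.norm(self.start.point - self.end.point)) / A

    def is_shallow(self, L_e: float) -> bool:
        return self.length < L_e


@dataclass
class ThreadingRecord:
    """Threading of ring ``threader`` through ring ``threaded``'s surface."""

    threader: int
    threaded: int
    contour_length: float           # total contour L of the threader (a)
    segments: list[ThreadingSegment] = field(default_factory=list)
    excluded: bool = False          # odd piercing count -> pair dropped
    repaired: int = 0               # crossings removed to restore alternation

    def retained(self, L_e: float = 0.0,
                 include_shallow: bool = True) -> list[ThreadingSegment]:
        if include_shallow:
            return list(self.segments)
        return [s for s in self.segments if not s.is_shallow(L_e)]

    def n_piercings(self, L_e: float = 0.0,
                    include_shallow: bool = True) -> int:
        """Crossings bordering at least one retained segment."""
        kept = self.retained(L_e, include_shallow)
        ids = set()
        for s in kept:
            ids.add(id(s.start))
            ids.add(id(s.end))
        return len(ids)

    def separation_length(self, L_e: float = 0.0,
                          include_shallow: bool = True) -> float:
        """Minority-side total contour length over retained segments."""
        kept = self.retained(L_e, include_shallow)
        if not kept:
            return 0.0
        side_len = {+1: 0.0, -1: 0.0}
        for s in kept:
            side_len[s.side] += s.length
        return min(side_len.values())

    def Q(self, L_e: float = 0.0, include_shallow: bool = True) -> float:
        """Minority-to-complement contour ratio, in [0, 1]."""
        lsep = self.separation_length(L_e, include_shallow)
        denom = self.contour_length - lsep
        return lsep / denom if denom > 0 else 0.0


def threading_segments(piercings: list[Piercing], contour_length: float,
                       threader: int = 0, threaded: int = 1,
                       ) -> ThreadingRecord:
    """Assemble a ThreadingRecord from the crossings of one ordered pair.

    Crossings are sorted along the threader's contour; consecutive
    crossings (cyclically) delimit segments, assigned to the side the
    entry crossing points into.  Valid crossing sequences alternate in
    sign; a non-alternating adjacent pair indicates a near-tangent
    double-detection and is repaired by removing both offending crossings
    (logged).  An odd remaining count marks the record as excluded.
    """
    rec = ThreadingRecord(threader=threader, threaded=threaded,
                          contour_length=contour_length)
    pts = sorted(piercings, key=lambda p: p.contour_pos)
    # repair: drop adjacent same-sign crossing pairs (near-tangent grazes)
    changed = True
    while changed and len(pts) >= 2:
        changed = False
        n = len(pts)
        best = None
        for i in range(n):
            j = (i + 1) % n
            if i != j and pts[i].sign == pts[j].sign:
                gap = (pts[j].contour_pos - pts[i].contour_pos) % contour_length
                if best is None or gap < best[0]:
                    best = (gap, i, j)
        if best is not None:
            _, i, j = best
            for k in sorted({i, j}, reverse=True):
                pts.pop(k)
            rec.repaired += 2
            changed = True
    if rec.repaired:
        log.info("pair (%d -> %d): removed %d non-alternating crossings",
                 threader, threaded, rec.repaired)
    if not pts:
        return rec
    if len(pts) % 2 == 1:
        log.warning("pair (%d -> %d): odd piercing count %d, excluded",
                    threader, threaded, len(pts))
        rec.excluded = True
        return rec
    n = len(pts)
    for i in range(n):
        p0, p1 = pts[i], pts[(i + 1) % n]
        length = (p1.contour_pos - p0.contour_pos) % contour_length
        if length == 0.0:
            length = contour_length
        rec.segments.append(ThreadingSegment(
            length=length, side=p0.sign, start=p0, end=p1))
    return rec


@dataclass
class ThreadingStatistics:
    n_t: float          # mean rings threaded per ring
    Q: float            # mean minority-contour ratio over threading pairs
    n_p: float          # mean piercings per threading (ordered) pair
    d: float            # mean piercing-pair distance per segment (a)
    n_pairs: int
    Q_values: np.ndarray = field(default_factory=lambda: np.array([]))
    d_values: np.ndarray = field(default_factory=lambda: np.array([]))


def threading_statistics(records: list[ThreadingRecord], n_rings: int,
                         L_e: float = 0.0, include_shallow: bool = True,
                         ) -> ThreadingStatistics:
    """Ensemble threading statistics over a snapshot's records.

    With ``include_shallow`` false, segments with L_t < L_e are removed
    before every average: a pair left with no retained segment no longer
    counts toward n_t, n_p or Q.  Averaging populations: n_t per ring;
    Q and n_p per ordered pair with at least one retained segment; d per
    retained segment.
    """
    threaded_by: dict[int, set[int]] = {i: set() for i in range(n_rings)}
    qs, nps, ds = [], [], []
    for rec in records:
        if rec.excluded:
            continue
        kept = rec.retained(L_e, include_shallow)
        if not kept:
            continue
        threaded_by[rec.threader].add(rec.threaded)
        qs.append(rec.Q(L_e, include_shallow))
        nps.append(rec.n_piercings(L_e, include_shallow))
        ds.extend(s.d for s in kept)
    n_t = float(np.mean([len(v) for v in threaded_by.values()])) if n_rings else 0.0
    return ThreadingStatistics(
        n_t=n_t,
        Q=float(np.mean(qs)) if qs else 0.0,
        n_p=float(np.mean(nps)) if nps else 0.0,
        d=float(np.mean(ds)) if ds else 0.0,
        n_pairs=len(qs),
        Q_values=np.array(qs),
        d_values=np.array(ds),
    )


def build_threading_graph(records: list[ThreadingRecord], n_rings: int,
                          L_e: float) -> nx.Graph:
    """Deep-threading network: edge when either ring of a pair threads the
    other with at least one segment of L_t > L_e.

    Node attribute ``n``: ring count; graph attributes ``components`` and
    ``largest_fraction`` summarize connectivity.
    """
    g = nx.Graph()
    g.add_nodes_from(range(n_rings))
    for rec in records:
        if rec.excluded or rec.threader == rec.threaded:
            continue
        deep = [s for s in rec.segments if s.length > L_e]
        if deep:
            g.add_edge(rec.threader, rec.threaded)
    comps = [len(c) for c in nx.connected_components(g)]
    g.graph["components"] = sorted(comps, reverse=True)
    g.graph["largest_fraction"] = max(comps) / n_rings if n_rings else 0.0
    return g
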