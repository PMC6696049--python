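"""Enumeration of 3-6 membered water rings in a hydrogen-bond graph.

A ring (one TWN instance) is a chordless simple cycle: consecutive members
are H-bonded and no H-bond exists between non-consecutive members.  The
chordless convention matches chemical ring perception and avoids counting
a triangle's enclosing quadrilateral as a second ring; an all-simple-cycles
mode is available for sensitivity analysis.

Each ring is reported once, in canonical form: lowest water index first,
then the lower of that water's two ring neighbours second.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ConfigError
from .io import Frame


@dataclass(frozen=True)
class WaterRing:
    """A canonicalized water ring in one frame."""

    members: tuple[int, ...]
    frame_index: int

    @property
    def size(self) -> int:
        return len(self.members)


def canonical_cycle(cycle: tuple[int, ...] | list[int]) -> tuple[int, ...]:
    """Rotate/reflect a cycle so the lowest index leads, lower neighbour next."""
    cycle = tuple(cycle)
    n = len(cycle)
    k = cycle.index(min(cycle))
    rot = cycle[k:] + cycle[:k]
    if rot[1] > rot[-1]:
        rot = (rot[0],) + rot[:0:-1]
    return rot


def enumerate_rings(
    graph: nx.Graph,
    min_size: int = 3,
    max_size: int = 6,
    chordless: bool = True,
) -> list[WaterRing]:
    """All rings of ``min_size``..``max_size`` waters, sorted canonically.

    With ``chordless=True`` (default) only chordless cycles are returned;
    otherwise every simple cycle in the size range is.
    """
    if not (3 <= min_size <= max_size <= 6):
        raise ConfigError(
            f"ring sizes must satisfy 3 <= min_size <= max_size <= 6, "
            f"got [{min_size}, {max_size}]"
        )
    frame_index = graph.graph.get("frame_index", -1)
    adj = {v: set(graph.neighbors(v)) for v in graph.nodes}
    found: set[tuple[int, ...]] = set()
    for cyc in _bounded_cycles(adj, max_size, chordless):
        if len(cyc) >= min_size:
            found.add(canonical_cycle(cyc))
    return [WaterRing(members=m, frame_index=frame_index) for m in sorted(found)]


def _bounded_cycles(adj, max_size, chordless):
    """DFS over simple cycles of length <= max_size.

    Cycles are rooted at their minimum node (path nodes all exceed the
    root).  In chordless mode a path is extended only while it remains an
    induced path whose interior avoids the root's neighbourhood, which
    yields exactly the chordless cycles without a post-filter.
    """
    for root in sorted(adj):
        root_nbrs = adj[root]
        stack = [(root, v, (root, v)) for v in sorted(root_nbrs) if v > root]
        while stack:
            prev, last, path = stack.pop()
            for nxt in adj[last]:
                if nxt <= root or nxt in path:
                    continue
                closes = nxt in root_nbrs
                if chordless:
                    # a chord is any edge from nxt into the path except to
                    # `last` (and to the root when closing)
                    chords = adj[nxt].intersection(path) - {last}
                    if closes:
                        if not chords - {root} and len(path) + 1 >= 3:
                            if path[1] < nxt:  # one orientation only
                                yield path + (nxt,)
                        continue  # extending past a root neighbour => chord
                    if chords:
                        continue
                else:
                    if closes and len(path) + 1 >= 3 and path[1] < nxt:
                        yield path + (nxt,)
                if len(path) + 1 < max_size:
                    stack.append((last, nxt, path + (nxt,)))


def ring_center(
    ring: WaterRing | tuple[int, ...], frame: Frame, mass_weighted: bool = False
) -> np.ndarray:
    """Center of a ring, minimum-image consistent when the frame has a box.

    By default the unweighted centroid of the member oxygens (oxygen carries
    16/18 of a water's mass, and hydrogen positions mostly add noise); with
    ``mass_weighted=True`` all nine sites enter with atomic masses.
    Members are unwrapped to the first member's periodic image before
    averaging, so rings straddling a boundary get a center on the cluster.
    """
    members = ring.members if isinstance(ring, WaterRing) else tuple(ring)
    for m in members:
        if m < 0 or m >= frame.n_waters:
            raise IndexError(f"ring member {m} outside frame ({frame.n_waters} waters)")
    idx = np.array(members)
    o = frame.o[idx]
    if frame.box is not None:
        o = o[0] + _min_image(o - o[0], frame.box)
    if not mass_weighted:
        return o.mean(axis=0)
    h1, h2 = frame.h1[idx], frame.h2[idx]
    if frame.box is not None:
        shift = o - frame.o[idx]  # reuse the oxygen unwrapping per member
        h1, h2 = h1 + shift, h2 + shift
    total = 15.999 * o + 1.008 * (h1 + h2)
    return total.sum(axis=0) / (len(idx) * (15.999 + 2 * 1.008))


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def rings_to_records(
    rings: list[WaterRing], frames: dict[int, Frame] | list[Frame]
) -> list[dict]:
    """Flat dict records (frame, size, members, residue ids, center) for export."""
    if isinstance(frames, list):
        frames = {f.index: f for f in frames}
    out = []
    for r in rings:
        fr = frames[r.frame_index]
        c = ring_center(r, fr)
        out.append(
            {
                "frame": r.frame_index,
                "size": r.size,
                "members": ",".join(str(m) for m in r.members),
                "residues": ",".join(fr.residue_ids[m] for m in r.members),
                "center_x": round(float(c[0]), 4),
                "center_y": round(float(c[1]), 4),
                "center_z": round(float(c[2]), 4),
            }
        )
    return out
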