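"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's vectorized/numpy code paths: plain
Python loops and networkx generators, so agreement is meaningful.
"""

from __future__ import annotations

import math

import networkx as nx

COULOMB = 332.0636
A_LJ = 582000.0
C_LJ = 595.0
CHARGES = (-0.834, 0.417, 0.417)


def reference_pair_energy(a, b, box=None) -> float:
    """Term-by-term 9-pair summation with scalar math only.

    Minimum image: the O-O displacement's integer image shift, applied to
    every site of molecule b (molecules stay rigid).
    """
    sa = [list(a.o_pos), list(a.h1_pos), list(a.h2_pos)]
    sb = [list(b.o_pos), list(b.h1_pos), list(b.h2_pos)]
    if box is not None:
        shift = [
            -box[k] * round((sb[0][k] - sa[0][k]) / box[k]) for k in range(3)
        ]
        sb = [[p[k] + shift[k] for k in range(3)] for p in sb]
    energy = 0.0
    for i in range(3):
        for j in range(3):
            r = math.dist(sa[i], sb[j])
            energy += COULOMB * CHARGES[i] * CHARGES[j] / r
    r_oo = math.dist(sa[0], sb[0])
    return energy + A_LJ / r_oo**12 - C_LJ / r_oo**6


def exhaustive_hbond_edges(frame, threshold=-2.25, prefilter=3.5):
    """O(n^2) H-bond edges: min-image O-O within prefilter AND energy <= threshold."""
    edges = set()
    box = None if frame.box is None else list(frame.box)
    for i in range(frame.n_waters):
        wi = frame.water(i)
        for j in range(i + 1, frame.n_waters):
            wj = frame.water(j)
            d = [wj.o_pos[k] - wi.o_pos[k] for k in range(3)]
            if box is not None:
                d = [d[k] - box[k] * round(d[k] / box[k]) for k in range(3)]
            if math.sqrt(sum(x * x for x in d)) > prefilter:
                continue
            if reference_pair_energy(wi, wj, box) <= threshold:
                edges.add((i, j))
    return edges


def exhaustive_energy_only_edges(frame, threshold=-2.25):
    """All-pairs H-bond edges with no distance condition at all."""
    edges = set()
    box = None if frame.box is None else list(frame.box)
    for i in range(frame.n_waters):
        wi = frame.water(i)
        for j in range(i + 1, frame.n_waters):
            if reference_pair_energy(wi, frame.water(j), box) <= threshold:
                edges.add((i, j))
    return edges


def _canonical(cycle):
    cycle = list(cycle)
    k = cycle.index(min(cycle))
    rot = cycle[k:] + cycle[:k]
    if rot[1] > rot[-1]:
        rot = [rot[0]] + rot[:0:-1]
    return tuple(rot)


def brute_force_rings(graph: nx.Graph, min_size=3, max_size=6, chordless=True):
    """All (chordless) simple cycles in the size window, canonicalized.

    Uses networkx's generic simple-cycle generator plus an explicit
    chord check, a completely different route from the package's DFS.
    """
    out = set()
    for cyc in nx.simple_cycles(graph, length_bound=max_size):
        if len(cyc) < min_size:
            continue
        if chordless and _has_chord(graph, cyc):
            continue
        out.add(_canonical(cyc))
    return out


def _has_chord(graph, cycle):
    n = len(cycle)
    members = set(cycle)
    for idx, v in enumerate(cycle):
        nbrs = set(graph.neighbors(v)) & members
        allowed = {cycle[(idx - 1) % n], cycle[(idx + 1) % n]}
        if nbrs - allowed:
            return True
    return False
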