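"""Water-water pair potential and hydrogen-bond graph construction.

Two 3-site waters interact through a Coulomb sum over all nine site pairs
plus a 12-6 Lennard-Jones term on the oxygen-oxygen distance:

    v(a, b) = k * sum_{i in a} sum_{j in b} q_i q_j / r_ij
              + A / r_oo^12 - C / r_oo^6

with A = 582,000 kcal A^12/mol, C = 595 kcal A^6/mol, q_O = -0.834 e,
q_H = +0.417 e and k = 332.0636 kcal A/(mol e^2), the standard conversion
for q_i q_j e^2 / r in these units.  A pair is hydrogen-bonded when
v(a, b) <= -2.25 kcal/mol (inclusive), an energy close to the minimum of
the pair-energy distribution of liquid water.

Periodic images: when a box is given, the minimum-image shift of the O-O
displacement is applied to all nine site pairs, keeping each molecule
rigid rather than imaging sites independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .errors import OverlapError
from .io import Frame, WaterMolecule

#: kcal*A/(mol*e^2); converts q_i*q_j*e^2/r to kcal/mol with r in Angstrom
COULOMB_CONSTANT = 332.0636


@dataclass(frozen=True)
class PotentialParams:
    """Parameters of the pairwise water potential and H-bond criterion."""

    A: float = 582000.0          # kcal A^12 / mol
    C: float = 595.0             # kcal A^6 / mol
    q_o: float = -0.834          # e
    q_h: float = 0.417           # e
    coulomb_constant: float = COULOMB_CONSTANT
    hbond_threshold: float = -2.25   # kcal/mol, inclusive
    distance_prefilter: float = 3.5  # A, O-O candidate cutoff

    def __post_init__(self) -> None:
        if self.A <= 0 or self.C <= 0 or self.coulomb_constant <= 0:
            raise ValueError("A, C and coulomb_constant must be positive")
        if self.hbond_threshold >= 0:
            raise ValueError("hbond_threshold must be negative")
        if abs(self.q_o + 2 * self.q_h) > 1e-9:
            raise ValueError("water must be neutral: q_O + 2 q_H = 0")
        if self.distance_prefilter < 3.2:
            raise ValueError("distance_prefilter below 3.2 A would drop H-bonds")

    @property
    def charges(self) -> np.ndarray:
        return np.array([self.q_o, self.q_h, self.q_h])


_MIN_OO = 0.1  # A; below this the molecules overlap unphysically


def pair_energy(
    a: WaterMolecule,
    b: WaterMolecule,
    params: PotentialParams = PotentialParams(),
    box: np.ndarray | None = None,
) -> float:
    """Interaction energy of one water pair in kcal/mol."""
    sa = a.sites
    sb = b.sites
    if box is not None:
        box = np.asarray(box, dtype=float)
        d_oo = sb[0] - sa[0]
        sb = sb - box * np.round(d_oo / box)
    r = np.linalg.norm(sa[:, None, :] - sb[None, :, :], axis=-1)
    r_oo = r[0, 0]
    if r_oo < _MIN_OO:
        raise OverlapError(f"O-O distance {r_oo:.3f} A below {_MIN_OO} A")
    q = params.charges
    coulomb = params.coulomb_constant * float(np.sum(np.outer(q, q) / r))
    lj = params.A / r_oo**12 - params.C / r_oo**6
    return coulomb + lj


def is_hbonded(
    a: WaterMolecule,
    b: WaterMolecule,
    params: PotentialParams = PotentialParams(),
    box: np.ndarray | None = None,
) -> bool:
    """True when the pair energy is at or below the H-bond threshold."""
    return pair_energy(a, b, params, box) <= params.hbond_threshold


def pair_energies(
    frame: Frame, pairs: np.ndarray, params: PotentialParams = PotentialParams()
) -> np.ndarray:
    """Vectorized pair energies for an (m, 2) array of water index pairs."""
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if pairs.size == 0:
        return np.empty(0)
    sites = frame.sites
    sa = sites[pairs[:, 0]]  # (m, 3, 3)
    sb = sites[pairs[:, 1]]
    if frame.box is not None:
        d_oo = sb[:, 0, :] - sa[:, 0, :]
        sb = sb - (frame.box * np.round(d_oo / frame.box))[:, None, :]
    r = np.linalg.norm(sa[:, :, None, :] - sb[:, None, :, :], axis=-1)  # (m,3,3)
    r_oo = r[:, 0, 0]
    if np.any(r_oo < _MIN_OO):
        k = int(np.argmin(r_oo))
        raise OverlapError(
            f"waters {pairs[k, 0]} and {pairs[k, 1]}: O-O distance "
            f"{r_oo[k]:.3f} A below {_MIN_OO} A"
        )
    q = params.charges
    coulomb = params.coulomb_constant * np.sum(np.outer(q, q)[None] / r, axis=(1, 2))
    lj = params.A / r_oo**12 - params.C / r_oo**6
    return coulomb + lj


def candidate_pairs(frame: Frame, cutoff: float) -> np.ndarray:
    """O-O pairs within ``cutoff`` (minimum image if the frame has a box)."""
    n = frame.n_waters
    if n < 2:
        return np.empty((0, 2), dtype=int)
    if frame.box is not None:
        pos = np.mod(frame.o, frame.box)
        # guard against coordinates landing exactly on the upper boundary
        pos = np.where(pos >= frame.box, 0.0, pos)
        tree = cKDTree(pos, boxsize=frame.box)
    else:
        tree = cKDTree(frame.o)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size == 0:
        return np.empty((0, 2), dtype=int)
    return pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]


def hbond_graph(
    frame: Frame, params: PotentialParams = PotentialParams()
) -> nx.Graph:
    """Per-frame hydrogen-bond graph on water indices.

    Candidate pairs are restricted to O-O <= ``distance_prefilter`` via a
    k-d tree; the result equals the all-pairs construction because pairs
    beyond the prefilter cannot reach the energy threshold.
    """
    g = nx.Graph(frame_index=frame.index)
    g.add_nodes_from(range(frame.n_waters))
    pairs = candidate_pairs(frame, params.distance_prefilter)
    if len(pairs):
        e = pair_energies(frame, pairs, params)
        bonded = pairs[e <= params.hbond_threshold]
        g.add_edges_from(map(tuple, bonded))
    return g
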