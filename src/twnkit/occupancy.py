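"""Binding-site restriction, ring-to-region assignment and occupancy stats.

Waters are first restricted to a sphere around the binding site (default
25 A, centered on the reference-ligand centroid).  Each ring found there
is attributed to the ligand region (head / linker / tail) whose nearest
labelled atom lies within the assignment cutoff of the ring center; rings
nearest to an L' atom are additionally flagged.  Percentages are reported
over assigned rings pooled across all frames.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .energetics import PotentialParams, hbond_graph
from .errors import LigandError
from .io import Frame, LigandModel
from .rings import WaterRing, enumerate_rings, ring_center

#: tie-break priority when a ring center is equidistant to several atoms
_PRIORITY = {"lprime": 0, "linker": 1, "head": 2, "tail": 3}


@dataclass(frozen=True)
class SiteSpec:
    """Binding-site sphere: explicit center (A) and radius (default 25 A)."""

    center: np.ndarray
    radius: float = 25.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        if self.radius <= 0:
            raise ValueError("site radius must be positive")

    @classmethod
    def around_ligand(cls, ligand: LigandModel, radius: float = 25.0) -> "SiteSpec":
        return cls(center=ligand.centroid, radius=radius)


@dataclass(frozen=True)
class RegionAssignment:
    ring: WaterRing
    region: str                 # head | linker | tail | unassigned
    distance: float             # A to the nearest labelled atom
    is_lprime: bool = False


def select_site_waters(frame: Frame, site: SiteSpec) -> tuple[Frame, np.ndarray]:
    """Restrict a frame to waters whose oxygen lies within the site sphere.

    Returns the subset frame (ordering preserved) and the index mapping
    from subset positions back to the original frame.  The boundary is
    inclusive: a water exactly at the radius is kept.
    """
    d = np.linalg.norm(frame.o - site.center, axis=1)
    keep = np.where(d <= site.radius)[0]
    if keep.size == 0:
        warnings.warn(
            f"frame {frame.index}: no waters within {site.radius} A of the site",
            stacklevel=2,
        )
    sub = Frame(
        index=frame.index,
        o=frame.o[keep],
        h1=frame.h1[keep],
        h2=frame.h2[keep],
        residue_ids=[frame.residue_ids[i] for i in keep],
        box=None if frame.box is None else frame.box.copy(),
        time=frame.time,
        solute_names=list(frame.solute_names),
        solute_pos=None if frame.solute_pos is None else frame.solute_pos.copy(),
        box_missing=frame.box_missing,
    )
    return sub, keep


def assign_ring(
    ring: WaterRing,
    frame: Frame,
    ligand: LigandModel,
    cutoff: float = 5.0,
    lprime_cutoff: float | None = None,
) -> RegionAssignment:
    """Attribute a ring to the region of the labelled atom nearest its center.

    Beyond ``cutoff`` the ring is unassigned.  Ties (within 1e-9 A) break
    by priority L' > linker > head > tail.  A ring whose nearest labelled
    atom is an L' atom (within ``lprime_cutoff``, default the assignment
    cutoff) is flagged ``is_lprime`` and counted as linker.
    """
    labeled = np.where(ligand.labeled_mask)[0]
    if labeled.size == 0:
        raise LigandError("ligand has no labelled atoms; cannot assign regions")
    center = ring_center(ring, frame)
    d = np.linalg.norm(ligand.coords[labeled] - center, axis=1)
    dmin = float(d.min())
    if dmin > cutoff:
        return RegionAssignment(ring, "unassigned", dmin)
    tied = labeled[d <= dmin + 1e-9]
    best = min(
        tied,
        key=lambda i: _PRIORITY["lprime" if ligand.lprime[i] else ligand.regions[i]],
    )
    if ligand.lprime[best]:
        lp_cut = cutoff if lprime_cutoff is None else lprime_cutoff
        return RegionAssignment(ring, "linker", dmin, is_lprime=dmin <= lp_cut)
    return RegionAssignment(ring, ligand.regions[best], dmin)


@dataclass
class OccupancyReport:
    """Pooled ring counts and percentages per ligand region."""

    counts: dict[str, int]
    percentages: dict[str, float]
    lprime_count: int
    lprime_fraction: float       # % of linker rings flagged L'
    n_frames: int
    n_assigned: int
    n_unassigned: int
    no_assigned_rings: bool
    size_counts: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "percentages": {k: round(v, 4) for k, v in self.percentages.items()},
            "lprime_count": self.lprime_count,
            "lprime_fraction": round(self.lprime_fraction, 4),
            "n_frames": self.n_frames,
            "n_assigned": self.n_assigned,
            "n_unassigned": self.n_unassigned,
            "no_assigned_rings": self.no_assigned_rings,
            "size_counts": {str(k): v for k, v in sorted(self.size_counts.items())},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def summarize_assignments(
    assignments: list[RegionAssignment], n_frames: int
) -> OccupancyReport:
    """Aggregate per-ring assignments into an occupancy report.

    Percentages use assigned rings as the denominator (unassigned rings,
    e.g. bulk-water rings inside the site sphere, are excluded).  With zero
    assigned rings all percentages are reported as 0 and flagged.
    """
    counts = {"head": 0, "linker": 0, "tail": 0}
    size_counts: dict[int, int] = {}
    lprime = 0
    unassigned = 0
    for a in assignments:
        if a.region == "unassigned":
            unassigned += 1
            continue
        counts[a.region] += 1
        size_counts[a.ring.size] = size_counts.get(a.ring.size, 0) + 1
        if a.is_lprime:
            lprime += 1
    total = sum(counts.values())
    if total:
        pct = {k: 100.0 * v / total for k, v in counts.items()}
    else:
        pct = {k: 0.0 for k in counts}
    lp_frac = 100.0 * lprime / counts["linker"] if counts["linker"] else 0.0
    return OccupancyReport(
        counts=counts,
        percentages=pct,
        lprime_count=lprime,
        lprime_fraction=lp_frac,
        n_frames=n_frames,
        n_assigned=total,
        n_unassigned=unassigned,
        no_assigned_rings=total == 0,
        size_counts=size_counts,
    )


def occupancy_report(
    frames: list[Frame],
    ligand: LigandModel,
    site: SiteSpec | None = None,
    params: PotentialParams = PotentialParams(),
    cutoff: float = 5.0,
    lprime_cutoff: float | None = None,
    min_size: int = 3,
    max_size: int = 6,
    chordless: bool = True,
    collect_rings: bool = False,
):
    """Full per-frame pipeline: site restriction, H-bond graph, rings, regions.

    Returns the :class:`OccupancyReport`, or ``(report, assignments,
    site_frames)`` when ``collect_rings`` is set.
    """
    if not frames:
        raise ValueError("occupancy_report needs at least one frame")
    if site is None:
        site = SiteSpec.around_ligand(ligand)
    assignments: list[RegionAssignment] = []
    site_frames: dict[int, Frame] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-site frames are fine here
        for frame in frames:
            sub, _ = select_site_waters(frame, site)
            site_frames[frame.index] = sub
            graph = hbond_graph(sub, params)
            for ring in enumerate_rings(graph, min_size, max_size, chordless):
                assignments.append(
                    assign_ring(ring, sub, ligand, cutoff, lprime_cutoff)
                )
    report = summarize_assignments(assignments, n_frames=len(frames))
    if collect_rings:
        return report, assignments, site_frames
    return report
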