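"""Volumetric shape similarity between a ligand and the TWN ensemble.

Both objects are rasterized onto the same boolean voxel grid (default
0.5 A spacing): ligand voxels lie within the Bondi van der Waals radius of
an in-scope atom, TWN voxels within a water probe radius (default 1.4 A)
of any ring-member oxygen, aggregated over frames.  The default score is
the ligand-coverage percentage 100 * |lig & twn| / |lig| — the fraction of
ligand (or region) volume overlapped by persistent water-ring density — so
a hydrophobic, never-hydrated region pulls the whole-ligand score down
while a heavily hydrated carbonyl region scores high.  A symmetric
Tanimoto mode (|intersection| / |union|) is available as well.

Only rings whose center of mass lies within a cutoff (default 2.0 A) of a
ligand heavy atom enter the TWN grid, mirroring the extraction of
ligand-proximal networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import LigandError, TwnError
from .io import Frame, LigandModel
from .rings import WaterRing, ring_center

#: Bondi van der Waals radii, A (fallback 1.7 for unlisted elements)
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "P": 1.80,
    "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98, "ZN": 1.39,
}
DEFAULT_SPACING = 0.5   # A
WATER_RADIUS = 1.4      # A, probe radius for ring-member oxygens
COM_CUTOFF = 2.0        # A, ring-center to ligand heavy atom


@dataclass
class OccupancyGrid:
    """Boolean voxel grid over the pocket."""

    origin: np.ndarray
    spacing: float
    occupied: np.ndarray  # bool, shape (nx, ny, nz)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        self.occupied = np.asarray(self.occupied, dtype=bool)
        if self.occupied.ndim != 3 or min(self.occupied.shape) < 1:
            raise ValueError("grid must be 3-D with positive dims")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.occupied.shape

    @property
    def n_occupied(self) -> int:
        return int(self.occupied.sum())

    def congruent(self, other: "OccupancyGrid") -> bool:
        return (
            self.dims == other.dims
            and abs(self.spacing - other.spacing) < 1e-9
            and np.allclose(self.origin, other.origin, atol=1e-9)
        )

    @classmethod
    def empty_like(cls, lo: np.ndarray, hi: np.ndarray, spacing: float) -> "OccupancyGrid":
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 1)
        return cls(origin=lo, spacing=spacing,
                   occupied=np.zeros(tuple(dims), dtype=bool))


@dataclass(frozen=True)
class SimilarityResult:
    percent: float
    scope: str
    n_rings_used: int
    mode: str = "coverage"


def grid_spec_for(
    ligand: LigandModel,
    spacing: float = DEFAULT_SPACING,
    padding: float = 2.0,
) -> OccupancyGrid:
    """Empty grid covering the ligand plus padding for probe radii."""
    pad = padding + max(VDW_RADII.values())
    return OccupancyGrid.empty_like(
        ligand.coords.min(axis=0) - pad, ligand.coords.max(axis=0) + pad, spacing
    )


def _mark_spheres(grid: OccupancyGrid, centers: np.ndarray, radii: np.ndarray) -> None:
    """Set voxels whose centers fall within radius of any sphere center."""
    occ = grid.occupied
    dims = np.array(occ.shape)
    for c, r in zip(centers, radii):
        lo = np.maximum(np.floor((c - r - grid.origin) / grid.spacing).astype(int), 0)
        hi = np.minimum(
            np.ceil((c + r - grid.origin) / grid.spacing).astype(int) + 1, dims
        )
        if np.any(lo >= hi):
            continue
        ax = [grid.origin[d] + grid.spacing * np.arange(lo[d], hi[d]) - c[d]
              for d in range(3)]
        d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= r * r


def voxelize_ligand(
    ligand: LigandModel,
    scope: str = "whole",
    grid: OccupancyGrid | None = None,
    spacing: float = DEFAULT_SPACING,
) -> OccupancyGrid:
    """Occupancy grid of the in-scope ligand atoms at their vdW radii."""
    mask = ligand.scope_mask(scope)
    if not mask.any():
        raise LigandError(f"scope {scope!r} selects no atoms")
    if grid is None:
        grid = grid_spec_for(ligand, spacing)
    out = OccupancyGrid(grid.origin, grid.spacing,
                        np.zeros(grid.dims, dtype=bool))
    centers = ligand.coords[mask]
    radii = np.array(
        [VDW_RADII.get(ligand.elements[i].upper(), 1.7)
         for i in np.where(mask)[0]]
    )
    _mark_spheres(out, centers, radii)
    return out


def proximal_rings(
    rings: list[WaterRing],
    frames: dict[int, Frame] | list[Frame],
    ligand: LigandModel,
    com_cutoff: float = COM_CUTOFF,
) -> list[WaterRing]:
    """Rings whose center lies within ``com_cutoff`` of a ligand heavy atom.

    The boundary is inclusive (a center exactly at the cutoff is kept).
    """
    if isinstance(frames, list):
        frames = {f.index: f for f in frames}
    heavy = ligand.coords[ligand.heavy_mask]
    if len(heavy) == 0:
        raise LigandError("ligand has no heavy atoms")
    kept = []
    for r in rings:
        c = ring_center(r, frames[r.frame_index])
        if np.linalg.norm(heavy - c, axis=1).min() <= com_cutoff:
            kept.append(r)
    return kept


def voxelize_twn(
    rings: list[WaterRing],
    frames: dict[int, Frame] | list[Frame],
    grid: OccupancyGrid,
    water_radius: float = WATER_RADIUS,
) -> OccupancyGrid:
    """Union occupancy of all ring-member oxygens across frames."""
    if isinstance(frames, list):
        frames = {f.index: f for f in frames}
    out = OccupancyGrid(grid.origin, grid.spacing,
                        np.zeros(grid.dims, dtype=bool))
    centers = []
    for r in rings:
        fr = frames[r.frame_index]
        for m in r.members:
            if m < 0 or m >= fr.n_waters:
                raise TwnError(
                    f"ring member {m} outside frame {r.frame_index}"
                )
            centers.append(fr.o[m])
    if centers:
        centers = np.asarray(centers)
        _mark_spheres(out, centers, np.full(len(centers), water_radius))
    return out


def shape_similarity(
    lig: OccupancyGrid,
    twn: OccupancyGrid,
    mode: str = "coverage",
    scope: str = "whole",
    n_rings_used: int = 0,
) -> SimilarityResult:
    """Percent similarity between ligand and TWN occupancy grids.

    ``coverage``: 100 * |lig & twn| / |lig| (default); ``tanimoto``:
    100 * |lig & twn| / |lig | twn|.
    """
    if not lig.congruent(twn):
        raise TwnError("ligand and TWN grids are not congruent")
    n_lig = lig.n_occupied
    if n_lig == 0:
        raise TwnError("ligand grid is empty; similarity undefined")
    inter = int((lig.occupied & twn.occupied).sum())
    if mode == "coverage":
        pct = 100.0 * inter / n_lig
    elif mode == "tanimoto":
        union = int((lig.occupied | twn.occupied).sum())
        pct = 100.0 * inter / union if union else 0.0
    else:
        raise TwnError(f"unknown similarity mode {mode!r}")
    return SimilarityResult(percent=pct, scope=scope,
                            n_rings_used=n_rings_used, mode=mode)


def write_dx(grid: OccupancyGrid, path) -> None:
    """Export a grid as OpenDX scalar volumetric text (0/1 values)."""
    nx, ny, nz = grid.dims
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.4f} {:.4f} {:.4f}\n".format(*grid.origin))
        fh.write(f"delta {grid.spacing:.4f} 0 0\n")
        fh.write(f"delta 0 {grid.spacing:.4f} 0\n")
        fh.write(f"delta 0 0 {grid.spacing:.4f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
        )
        flat = grid.occupied.astype(float).ravel()
        for k in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.1f}" for v in flat[k:k + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
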