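"""Synthetic water scenes with known ground truth.

Everything downstream (H-bond criterion, ring enumeration, region
occupancy, shape similarity) is testable against these fixtures without an
MD engine: rings of 3-6 waters are planted at controlled positions with
ideal linear H-bond geometry, noise waters are scattered at safe
distances, and a toy rod-shaped multi-region ligand provides head /
linker / tail / L' labels.

Planted geometry is validated against the energetic criterion at
generation time (not assumed), so the fixtures stay coupled to the actual
potential.  Every stochastic generator takes a seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .energetics import PotentialParams, pair_energy
from .errors import GenerationError
from .io import Frame, LigandModel, WaterMolecule
from .occupancy import OccupancyReport, SiteSpec, assign_ring
from .rings import WaterRing

#: rigid water geometry used for all generated molecules
OH_BOND = 0.9572          # A
HOH_ANGLE = 104.52        # degrees


def _water_sites(o: np.ndarray, h1_dir: np.ndarray, second_dir: np.ndarray):
    """O/H1/H2 positions given the donor direction and an out-of-plane axis."""
    h1_dir = h1_dir / np.linalg.norm(h1_dir)
    second_dir = second_dir - np.dot(second_dir, h1_dir) * h1_dir
    second_dir /= np.linalg.norm(second_dir)
    ang = np.radians(HOH_ANGLE)
    h2_dir = np.cos(ang) * h1_dir + np.sin(ang) * second_dir
    return o, o + OH_BOND * h1_dir, o + OH_BOND * h2_dir


def ideal_dimer(o_o: float = 2.8) -> tuple[WaterMolecule, WaterMolecule]:
    """Canonical linear H-bond dimer: donor O-H aimed at the acceptor O."""
    od = np.zeros(3)
    oa = np.array([o_o, 0.0, 0.0])
    d = _water_sites(od, np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]))
    half = np.radians(HOH_ANGLE / 2)
    # acceptor hydrogens point away from the donor, splayed about +x
    a1 = np.array([np.cos(half), np.sin(half), 0.0])
    a2 = np.array([np.cos(half), -np.sin(half), 0.0])
    a = (oa, oa + OH_BOND * a1, oa + OH_BOND * a2)
    return WaterMolecule(*d), WaterMolecule(*a)


def _orthonormal_basis(normal: np.ndarray):
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    ref = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2, n


#: donor-hydrogen bend (degrees, away from the edge toward the ring
#: exterior) per ring size; small rings need bent H-bonds, as real cyclic
#: water clusters do, to keep the neighbour's sites out of repulsion range
_DONOR_BEND = {3: 15.0, 4: 5.0, 5: 0.0, 6: 0.0}


def make_ring(
    size: int,
    center: np.ndarray = (0.0, 0.0, 0.0),
    normal: np.ndarray = (0.0, 0.0, 1.0),
    o_o_distance: float = 2.75,
    params: PotentialParams = PotentialParams(),
    validate: bool = True,
) -> list[WaterMolecule]:
    """A planar ring of ``size`` waters H-bonded along the edges.

    Oxygens sit at the vertices of a regular polygon with the requested
    O-O edge length; each water donates one hydrogen along the edge to its
    clockwise neighbour (bent slightly outward for small rings), the free
    hydrogen points radially outward in the ring plane.  The result is
    self-checked against the potential: every cyclically adjacent pair
    must satisfy the energetic H-bond criterion and (for size >= 4) no
    non-adjacent pair may.
    """
    if not 3 <= size <= 6:
        raise GenerationError(f"ring size must be 3..6, got {size}")
    center = np.asarray(center, dtype=float)
    e1, e2, n = _orthonormal_basis(normal)
    radius = o_o_distance / (2.0 * np.sin(np.pi / size))
    verts = [
        center + radius * (np.cos(2 * np.pi * k / size) * e1
                           + np.sin(2 * np.pi * k / size) * e2)
        for k in range(size)
    ]
    bend = np.radians(_DONOR_BEND[size])
    waters = []
    for k in range(size):
        edge = verts[(k + 1) % size] - verts[k]
        edge /= np.linalg.norm(edge)
        out = verts[k] - center
        out = out - np.dot(out, edge) * edge
        out /= np.linalg.norm(out)
        donor_dir = np.cos(bend) * edge + np.sin(bend) * out
        waters.append(WaterMolecule(*_water_sites(verts[k], donor_dir, out)))
    if validate:
        for i in range(size):
            for j in range(i + 1, size):
                adjacent = (j - i == 1) or (i == 0 and j == size - 1)
                e = pair_energy(waters[i], waters[j], params)
                if adjacent and e > params.hbond_threshold:
                    raise GenerationError(
                        f"ring size {size}: edge ({i},{j}) energy {e:.2f} "
                        f"kcal/mol fails the H-bond criterion"
                    )
                if not adjacent and e <= params.hbond_threshold:
                    raise GenerationError(
                        f"ring size {size}: non-adjacent pair ({i},{j}) "
                        f"energy {e:.2f} kcal/mol would form a chord"
                    )
    return waters


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


_TEMPLATE = np.array(_water_sites(np.zeros(3), np.array([1.0, 0.0, 0.0]),
                                  np.array([0.0, 1.0, 0.0])))


def make_box(
    n: int,
    box: float | np.ndarray,
    min_oo: float = 2.6,
    seed: int = 0,
    max_tries: int = 20000,
) -> Frame:
    """A periodic box of ``n`` randomly placed, randomly oriented waters.

    Oxygen positions are drawn by rejection sampling so no minimum-image
    O-O distance falls below ``min_oo``.  Deterministic for a fixed seed.
    """
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"could not place {n} waters with min O-O {min_oo} A in box "
                f"{box} after {max_tries} attempts"
            )
        cand = rng.uniform(0.0, 1.0, size=3) * box
        ok = True
        for p in placed:
            d = cand - p
            d -= box * np.round(d / box)
            if np.dot(d, d) < min_oo * min_oo:
                ok = False
                break
        if ok:
            placed.append(cand)
    o, h1, h2 = [], [], []
    for p in placed:
        rot = _random_rotation(rng)
        sites = _TEMPLATE @ rot.T + p
        o.append(sites[0]); h1.append(sites[1]); h2.append(sites[2])
    return Frame(
        index=0,
        o=np.array(o).reshape(-1, 3),
        h1=np.array(h1).reshape(-1, 3),
        h2=np.array(h2).reshape(-1, 3),
        box=box,
    )


def make_toy_ligand(
    n_head: int = 4,
    n_linker: int = 4,
    n_tail: int = 4,
    spacing: float = 2.5,
    name: str = "toy-rod",
) -> LigandModel:
    """Collinear rod ligand with contiguous head/linker/tail segments.

    One linker atom (mid-linker, carbon replaced by oxygen) carries the L'
    flag, mimicking a linker carbonyl joining linker and head.
    """
    n = n_head + n_linker + n_tail
    coords = np.zeros((n, 3))
    coords[:, 0] = spacing * np.arange(n)
    regions = (["head"] * n_head + ["linker"] * n_linker + ["tail"] * n_tail)
    lprime = np.zeros(n, dtype=bool)
    lp = n_head + (n_linker - 1) // 2
    lprime[lp] = True
    elements = ["C"] * n
    elements[lp] = "O"
    return LigandModel(name=name, elements=elements, coords=coords,
                       regions=regions, lprime=lprime)


# ---------------------------------------------------------------------------
# planted scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantSpec:
    """Counts of rings to plant per ligand region across a scene.

    ``n_lprime`` rings are placed nearest the L' atom (they count as
    linker); ``n_linker`` rings sit near plain linker atoms.  Noise waters
    are scattered inside the site sphere but far from the ligand and from
    every planted water, so they can only ever produce unassigned rings.
    """

    n_head: int = 0
    n_linker: int = 0
    n_lprime: int = 0
    n_tail: int = 0
    noise_per_frame: int = 8
    seed: int = 0


@dataclass
class PlantedScene:
    frames: list[Frame]
    ligand: LigandModel
    truth: OccupancyReport
    planted_rings: list[WaterRing] = field(default_factory=list)


# slot table for the default 12-atom rod (spacing 2.5): placement offset,
# target region, admissible ring sizes (kept small in crowded slots so
# inter-ring O-O distances stay above the H-bond prefilter)
_SLOTS = (
    ("head", np.array([-3.5, 0.0, 0.0]), (3, 4, 5, 6)),
    ("head", np.array([5.0, 4.7, 0.0]), (3, 4)),
    ("linker", np.array([10.0, -4.7, 0.0]), (3,)),
    ("linker", np.array([17.5, 4.7, 0.0]), (3,)),
    ("lprime", np.array([12.5, 0.0, 4.75]), (3, 4, 5)),
    ("lprime", np.array([12.5, 0.0, -4.75]), (3, 4, 5)),
    ("tail", np.array([31.0, 0.0, 0.0]), (3, 4, 5, 6)),
)

_NORMALS = (
    np.array([0.0, 0.0, 1.0]),
    np.array([0.0, 1.0, 0.0]),
    np.array([1.0, 0.0, 0.0]),
    np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0),
)

_NOISE_LIGAND_MIN = 8.5   # A; keeps any noise-ring centroid > 5 A from atoms
_NOISE_RING_MIN = 4.5     # A; no H-bond edges between noise and planted waters


def plant_scene(
    spec: PlantSpec,
    ligand: LigandModel | None = None,
    params: PotentialParams = PotentialParams(),
    site_radius: float = 25.0,
    assign_cutoff: float = 5.0,
) -> PlantedScene:
    """Generate frames with planted rings plus the ground-truth report.

    Rings are distributed over as many frames as the per-frame slot table
    allows (at most two rings per region per frame); every frame is
    self-checked: planted edges satisfy the H-bond criterion, no spurious
    inter-ring contact comes within the prefilter distance, and each ring
    center assigns to its intended region under the nearest-labelled-atom
    rule.  Ground truth is computed from the spec by construction.
    """
    if ligand is None:
        ligand = make_toy_ligand()
    queues = {
        "head": spec.n_head, "linker": spec.n_linker,
        "lprime": spec.n_lprime, "tail": spec.n_tail,
    }
    if any(v < 0 for v in queues.values()):
        raise GenerationError("ring counts must be non-negative")
    rng = np.random.default_rng(spec.seed)
    slot_counts = [0] * len(_SLOTS)
    normal_counter = itertools.count()
    frames: list[Frame] = []
    planted: list[WaterRing] = []
    size_counts: dict[int, int] = {}
    while any(queues.values()):
        frame_waters: list[WaterMolecule] = []
        ring_specs: list[tuple[str, tuple[int, ...]]] = []
        centers: list[np.ndarray] = []
        for slot_no, (region, offset, sizes) in enumerate(_SLOTS):
            if queues[region] <= 0:
                continue
            queues[region] -= 1
            size = sizes[slot_counts[slot_no] % len(sizes)]
            slot_counts[slot_no] += 1
            normal = _NORMALS[next(normal_counter) % len(_NORMALS)]
            waters = make_ring(size, center=offset, normal=normal,
                               params=params, validate=True)
            start = len(frame_waters)
            frame_waters.extend(waters)
            ring_specs.append((region, tuple(range(start, start + size))))
            centers.append(offset)
            size_counts[size] = size_counts.get(size, 0) + 1
        frame = _assemble_scene_frame(
            len(frames), frame_waters, ligand, spec.noise_per_frame, rng,
            site_radius, params,
        )
        _check_scene_frame(frame, ring_specs, centers, ligand, params,
                           assign_cutoff)
        for region, members in ring_specs:
            planted.append(WaterRing(members=members, frame_index=frame.index))
        frames.append(frame)
    truth = _truth_report(spec, len(frames), size_counts)
    return PlantedScene(frames=frames, ligand=ligand, truth=truth,
                        planted_rings=planted)


def _assemble_scene_frame(index, waters, ligand, n_noise, rng, site_radius,
                          params):
    site = SiteSpec.around_ligand(ligand, radius=site_radius)
    planted_o = np.array([w.o_pos for w in waters]).reshape(-1, 3)
    noise_o: list[np.ndarray] = []
    tries = 0
    while len(noise_o) < n_noise:
        tries += 1
        if tries > 2000 * max(n_noise, 1):
            raise GenerationError("could not place noise waters")
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = (site_radius - 1.0) * rng.uniform() ** (1.0 / 3.0)
        cand = site.center + r * u
        if np.linalg.norm(ligand.coords - cand, axis=1).min() < _NOISE_LIGAND_MIN:
            continue
        if len(planted_o) and np.linalg.norm(planted_o - cand, axis=1).min() < _NOISE_RING_MIN:
            continue
        if noise_o and np.linalg.norm(np.array(noise_o) - cand, axis=1).min() < 2.6:
            continue
        noise_o.append(cand)
    all_w = list(waters)
    for p in noise_o:
        rot = _random_rotation(rng)
        sites = _TEMPLATE @ rot.T + p
        all_w.append(WaterMolecule(sites[0], sites[1], sites[2]))
    return Frame(
        index=index,
        o=np.array([w.o_pos for w in all_w]).reshape(-1, 3),
        h1=np.array([w.h1_pos for w in all_w]).reshape(-1, 3),
        h2=np.array([w.h2_pos for w in all_w]).reshape(-1, 3),
    )


def _check_scene_frame(frame, ring_specs, centers, ligand, params, cutoff):
    # planted ring centers must honour the isolation invariant ...
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            d = np.linalg.norm(centers[i] - centers[j])
            if d <= 2.0 * params.distance_prefilter:
                raise GenerationError(
                    f"planted ring centers {d:.2f} A apart violate the "
                    f"2x-prefilter isolation invariant"
                )
    # ... and no inter-ring oxygen pair may come near the prefilter
    for (ra, ma), (rb, mb) in itertools.combinations(ring_specs, 2):
        da = frame.o[list(ma)][:, None, :] - frame.o[list(mb)][None, :, :]
        if np.min(np.linalg.norm(da, axis=-1)) <= params.distance_prefilter + 0.05:
            raise GenerationError("inter-ring O-O contact inside the prefilter")
    # every planted ring must assign to its intended region
    for region, members in ring_specs:
        ring = WaterRing(members=members, frame_index=frame.index)
        a = assign_ring(ring, frame, ligand, cutoff=cutoff)
        want = "linker" if region == "lprime" else region
        if a.region != want or a.is_lprime != (region == "lprime"):
            raise GenerationError(
                f"planted {region} ring assigned to {a.region} "
                f"(lprime={a.is_lprime})"
            )


def _fibonacci_directions(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def plant_proximal_shell(
    n_frames: int,
    ligand: LigandModel | None = None,
    offset: float = 1.2,
    scope: str = "lprime",
    params: PotentialParams = PotentialParams(),
) -> PlantedScene:
    """Frames with one ring per frame hugging a ligand scope.

    Ring centers sit ``offset`` Angstrom from an in-scope atom (inside the
    2 A center-of-mass extraction cutoff), with directions spread over a
    Fibonacci sphere and sizes cycling 3..6 — an idealized stand-in for a
    persistently hydrated site, used to exercise shape similarity.
    """
    if ligand is None:
        ligand = make_toy_ligand()
    anchors = ligand.coords[ligand.scope_mask(scope)]
    if len(anchors) == 0:
        raise GenerationError(f"scope {scope!r} selects no ligand atoms")
    dirs = _fibonacci_directions(max(n_frames, 1))
    frames: list[Frame] = []
    planted: list[WaterRing] = []
    for i in range(n_frames):
        anchor = anchors[i % len(anchors)]
        size = 3 + i % 4
        normal = _NORMALS[i % len(_NORMALS)]
        waters = make_ring(size, center=anchor + offset * dirs[i],
                           normal=normal, params=params)
        frames.append(Frame(
            index=i,
            o=np.array([w.o_pos for w in waters]),
            h1=np.array([w.h1_pos for w in waters]),
            h2=np.array([w.h2_pos for w in waters]),
        ))
        planted.append(WaterRing(members=tuple(range(size)), frame_index=i))
    truth = _truth_report(
        PlantSpec(**{
            {"head": "n_head", "linker": "n_linker",
             "lprime": "n_lprime", "tail": "n_tail"}[scope]: n_frames
        }),
        n_frames, {},
    )
    return PlantedScene(frames=frames, ligand=ligand, truth=truth,
                        planted_rings=planted)


def _truth_report(spec: PlantSpec, n_frames: int, size_counts) -> OccupancyReport:
    counts = {
        "head": spec.n_head,
        "linker": spec.n_linker + spec.n_lprime,
        "tail": spec.n_tail,
    }
    total = sum(counts.values())
    pct = ({k: 100.0 * v / total for k, v in counts.items()} if total
           else {k: 0.0 for k in counts})
    lp_frac = 100.0 * spec.n_lprime / counts["linker"] if counts["linker"] else 0.0
    return OccupancyReport(
        counts=counts,
        percentages=pct,
        lprime_count=spec.n_lprime,
        lprime_fraction=lp_frac,
        n_frames=n_frames,
        n_assigned=total,
        n_unassigned=0,
        no_assigned_rings=total == 0,
        size_counts=size_counts,
    )
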