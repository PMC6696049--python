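"""Reading and writing MD snapshots and reference ligands.

Frames of explicit 3-site waters are read from multi-model PDB files
(delegated to MDAnalysis) or from single- or multi-frame concatenated GRO
files (parsed directly: the concatenated dialect and line-numbered error
reporting require direct access to the fixed-width records).  Coordinates
are stored in Angstrom throughout; GRO values (nm) are converted on read.

Only orthorhombic boxes are supported.  Waters are identified by residue
name, not connectivity, so trajectories without CONECT records work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import LigandError, TrajectoryParseError, TriclinicBoxError

DEFAULT_WATER_RESNAMES = frozenset({"SOL", "HOH", "WAT", "TIP3", "SPC"})

#: region labels a ligand atom may carry; L' atoms are linker atoms with an
#: extra flag (the linker carbonyl position where linker and head connect)
REGION_LABELS = ("head", "linker", "tail")

_LPRIME_ALIASES = {"l'", "lprime", "l′", "l`"}


@dataclass(frozen=True)
class WaterMolecule:
    """One rigid 3-site water: oxygen plus two hydrogens, Angstrom."""

    o_pos: np.ndarray
    h1_pos: np.ndarray
    h2_pos: np.ndarray
    residue_id: str = ""

    @property
    def sites(self) -> np.ndarray:
        """(3, 3) array of O, H1, H2 positions."""
        return np.stack([self.o_pos, self.h1_pos, self.h2_pos])


@dataclass
class Frame:
    """One trajectory snapshot: water coordinates plus optional solute/box.

    ``o``, ``h1``, ``h2`` are (n, 3) float arrays; ``box`` holds three
    orthorhombic box lengths in Angstrom or ``None`` when the source file
    carried no box (``box_missing`` is then set).
    """

    index: int
    o: np.ndarray
    h1: np.ndarray
    h2: np.ndarray
    residue_ids: list[str] = field(default_factory=list)
    box: np.ndarray | None = None
    time: float | None = None
    solute_names: list[str] = field(default_factory=list)
    solute_pos: np.ndarray | None = None
    box_missing: bool = False

    def __post_init__(self) -> None:
        self.o = np.asarray(self.o, dtype=float).reshape(-1, 3)
        self.h1 = np.asarray(self.h1, dtype=float).reshape(-1, 3)
        self.h2 = np.asarray(self.h2, dtype=float).reshape(-1, 3)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise TrajectoryParseError(
                    f"frame {self.index}: non-positive box lengths {self.box}"
                )
        if not self.residue_ids:
            self.residue_ids = [str(i + 1) for i in range(len(self.o))]

    @property
    def n_waters(self) -> int:
        return len(self.o)

    @property
    def sites(self) -> np.ndarray:
        """(n, 3, 3) array: water, site (O/H1/H2), xyz."""
        return np.stack([self.o, self.h1, self.h2], axis=1)

    def water(self, i: int) -> WaterMolecule:
        return WaterMolecule(self.o[i], self.h1[i], self.h2[i], self.residue_ids[i])

    @property
    def waters(self) -> list[WaterMolecule]:
        return [self.water(i) for i in range(self.n_waters)]

    def validate(self) -> None:
        """Check O-H bond lengths (minimum-image if a box is present)."""
        for h in (self.h1, self.h2):
            d = h - self.o
            if self.box is not None:
                d -= self.box * np.round(d / self.box)
            r = np.linalg.norm(d, axis=1)
            bad = np.where((r < 0.5) | (r > 1.5))[0]
            if bad.size:
                rid = self.residue_ids[bad[0]]
                raise TrajectoryParseError(
                    f"frame {self.index}: water residue {rid} has O-H distance "
                    f"{r[bad[0]]:.3f} A outside [0.5, 1.5]"
                )


@dataclass
class LigandModel:
    """Reference ligand: elements, 3D coordinates and region labels.

    ``regions[i]`` is one of head/linker/tail/unlabeled; ``lprime[i]`` flags
    linker atoms at the L' position (carbonyl joining linker and head).
    """

    name: str
    elements: list[str]
    coords: np.ndarray
    regions: list[str] = field(default_factory=list)
    lprime: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.coords) == 0:
            raise LigandError(f"ligand {self.name!r} has no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise LigandError(f"ligand {self.name!r} has non-finite coordinates")
        if not self.regions:
            self.regions = ["unlabeled"] * len(self.coords)
        if self.lprime is None:
            self.lprime = np.zeros(len(self.coords), dtype=bool)
        self.lprime = np.asarray(self.lprime, dtype=bool)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def labeled_mask(self) -> np.ndarray:
        return np.array([r != "unlabeled" for r in self.regions])

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.elements])

    def scope_mask(self, scope: str) -> np.ndarray:
        """Atom mask for a similarity/occupancy scope.

        ``whole`` selects every atom; ``lprime`` the flagged linker atoms;
        region names select their labelled atoms.
        """
        if scope == "whole":
            return np.ones(self.n_atoms, dtype=bool)
        if scope == "lprime":
            return self.lprime.copy()
        if scope in REGION_LABELS:
            return np.array([r == scope for r in self.regions])
        raise LigandError(f"unknown scope {scope!r}")

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


# ---------------------------------------------------------------------------
# frame readers
# ---------------------------------------------------------------------------

def read_frames(
    path: str | Path,
    format: str | None = None,
    water_resnames: frozenset[str] | set[str] = DEFAULT_WATER_RESNAMES,
) -> list[Frame]:
    """Read all frames from a multi-model PDB or (multi-frame) GRO file.

    Waters are assembled O/H1/H2 per residue; any water residue without
    exactly one oxygen and two hydrogens raises.  Non-water atoms are kept
    on each frame for optional site centering.  A missing box sets
    ``Frame.box_missing`` and emits a warning.
    """
    path = Path(path)
    if not path.exists():
        raise TrajectoryParseError(f"no such file: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        frames = _read_pdb_frames(path, frozenset(water_resnames))
    elif fmt == "gro":
        frames = _read_gro_frames(path, frozenset(water_resnames))
    else:
        raise TrajectoryParseError(f"unsupported trajectory format {fmt!r}")
    for fr in frames:
        fr.validate()
    return frames


def _prescan_pdb(path: Path) -> None:
    """Validate coordinate fields so malformed records name a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except (ValueError, IndexError):
                    raise TrajectoryParseError(
                        f"{path}:{lineno}: malformed coordinate record: "
                        f"{line.rstrip()!r}"
                    ) from None


def _read_pdb_frames(path: Path, resnames: frozenset[str]) -> list[Frame]:
    import MDAnalysis as mda

    _prescan_pdb(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as err:  # MDAnalysis raises many concrete types
            raise TrajectoryParseError(f"failed to parse {path}: {err}") from err

    water_res, solute_idx = [], []
    for res in u.residues:
        if res.resname.strip() in resnames:
            if len(res.atoms) != 3:
                raise TrajectoryParseError(
                    f"{path}: water residue {res.resname} {res.resid} has "
                    f"{len(res.atoms)} atoms (expected 3)"
                )
            names = [a.name.strip().upper() for a in res.atoms]
            o_local = [k for k, n in enumerate(names) if n.startswith("O")]
            if len(o_local) != 1:
                raise TrajectoryParseError(
                    f"{path}: water residue {res.resname} {res.resid} does "
                    f"not have exactly one oxygen (atom names {names})"
                )
            idx = res.atoms.indices
            o = idx[o_local[0]]
            h = [idx[k] for k in range(3) if k != o_local[0]]
            water_res.append((f"{res.resname.strip()}{res.resid}", o, h[0], h[1]))
        else:
            solute_idx.extend(res.atoms.indices)
    solute_idx = np.array(solute_idx, dtype=int)
    solute_names = [u.atoms[i].name for i in solute_idx]

    frames = []
    missing_box = False
    for ts in u.trajectory:
        box, box_missing = _check_box(ts.dimensions, path)
        missing_box |= box_missing
        pos = ts.positions
        frames.append(
            Frame(
                index=len(frames),
                o=pos[[w[1] for w in water_res]] if water_res else np.empty((0, 3)),
                h1=pos[[w[2] for w in water_res]] if water_res else np.empty((0, 3)),
                h2=pos[[w[3] for w in water_res]] if water_res else np.empty((0, 3)),
                residue_ids=[w[0] for w in water_res],
                box=box,
                solute_names=list(solute_names),
                solute_pos=pos[solute_idx].copy() if len(solute_idx) else None,
                box_missing=box_missing,
            )
        )
    if missing_box:
        warnings.warn(f"{path}: no box information; periodicity disabled", stacklevel=3)
    return frames


def _check_box(dims, path) -> tuple[np.ndarray | None, bool]:
    if dims is None or not np.any(np.asarray(dims)[:3]):
        return None, True
    dims = np.asarray(dims, dtype=float)
    if len(dims) >= 6 and not np.allclose(dims[3:6], 90.0, atol=1e-3):
        raise TriclinicBoxError(
            f"{path}: triclinic box (angles {dims[3:6]}) is not supported"
        )
    return dims[:3].copy(), False


def _read_gro_frames(path: Path, resnames: frozenset[str]) -> list[Frame]:
    frames: list[Frame] = []
    missing_box = False
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i].rstrip("\n")
        time = None
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                pass
        try:
            natoms = int(lines[i + 1])
        except (ValueError, IndexError):
            raise TrajectoryParseError(
                f"{path}:{i + 2}: expected atom count, got "
                f"{lines[i + 1].rstrip()!r}" if i + 1 < len(lines)
                else f"{path}: truncated file"
            ) from None
        atom_lines = lines[i + 2 : i + 2 + natoms]
        if len(atom_lines) < natoms or i + 2 + natoms >= len(lines) + 1:
            raise TrajectoryParseError(f"{path}: truncated frame at line {i + 1}")
        records = []
        for k, line in enumerate(atom_lines):
            lineno = i + 3 + k
            try:
                resid = int(line[0:5])
                resname = line[5:10].strip()
                atname = line[10:15].strip()
                xyz = np.array(
                    [float(line[20:28]), float(line[28:36]), float(line[36:44])]
                ) * 10.0  # nm -> A
            except (ValueError, IndexError):
                raise TrajectoryParseError(
                    f"{path}:{lineno}: malformed GRO atom record: {line.rstrip()!r}"
                ) from None
            records.append((resid, resname, atname, xyz))
        box_line = lines[i + 2 + natoms]
        try:
            vals = [float(v) for v in box_line.split()]
        except ValueError:
            raise TrajectoryParseError(
                f"{path}:{i + 3 + natoms}: malformed box line: {box_line.rstrip()!r}"
            ) from None
        if len(vals) > 3 and any(abs(v) > 1e-9 for v in vals[3:]):
            raise TriclinicBoxError(f"{path}: triclinic box is not supported")
        box = np.array(vals[:3]) * 10.0
        box_missing = bool(np.all(box == 0.0))
        if box_missing:
            box = None
            missing_box = True
        frames.append(_assemble_gro_frame(len(frames), records, box, time,
                                          box_missing, resnames, path))
        i += 2 + natoms + 1
    if missing_box:
        warnings.warn(f"{path}: no box information; periodicity disabled", stacklevel=3)
    return frames


def _assemble_gro_frame(index, records, box, time, box_missing, resnames, path):
    o, h1, h2, rids = [], [], [], []
    sol_names, sol_pos = [], []
    # group consecutive records sharing (resid, resname)
    groups: list[list] = []
    prev = None
    for rec in records:
        key = (rec[0], rec[1])
        if key != prev:
            groups.append([])
            prev = key
        groups[-1].append(rec)
    for grp in groups:
        resid, resname = grp[0][0], grp[0][1]
        if resname in resnames:
            if len(grp) != 3:
                raise TrajectoryParseError(
                    f"{path}: water residue {resname}{resid} has {len(grp)} "
                    f"atoms (expected 3)"
                )
            o_local = [k for k, g in enumerate(grp) if g[2].upper().startswith("O")]
            if len(o_local) != 1:
                raise TrajectoryParseError(
                    f"{path}: water residue {resname}{resid} does not have "
                    f"exactly one oxygen"
                )
            hs = [g for k, g in enumerate(grp) if k != o_local[0]]
            o.append(grp[o_local[0]][3])
            h1.append(hs[0][3])
            h2.append(hs[1][3])
            rids.append(f"{resname}{resid}")
        else:
            for g in grp:
                sol_names.append(g[2])
                sol_pos.append(g[3])
    return Frame(
        index=index,
        o=np.array(o) if o else np.empty((0, 3)),
        h1=np.array(h1) if h1 else np.empty((0, 3)),
        h2=np.array(h2) if h2 else np.empty((0, 3)),
        residue_ids=rids,
        box=box,
        time=time,
        solute_names=sol_names,
        solute_pos=np.array(sol_pos) if sol_pos else None,
        box_missing=box_missing,
    )


# ---------------------------------------------------------------------------
# frame writers
# ---------------------------------------------------------------------------

def write_gro(frames: list[Frame], path: str | Path, title: str = "twnkit frame") -> None:
    """Write frames as a concatenated GRO file (nm, fixed-width)."""
    with open(path, "w") as fh:
        for fr in frames:
            t = f" t= {fr.time:.3f}" if fr.time is not None else ""
            fh.write(f"{title}{t}\n")
            n = 3 * fr.n_waters + (len(fr.solute_names) if fr.solute_pos is not None else 0)
            fh.write(f"{n:5d}\n")
            serial = 0
            for i in range(fr.n_waters):
                for name, pos in (("OW", fr.o[i]), ("HW1", fr.h1[i]), ("HW2", fr.h2[i])):
                    serial += 1
                    x, y, z = pos / 10.0
                    fh.write(f"{i + 1:5d}{'SOL':<5s}{name:>5s}{serial % 100000:5d}"
                             f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
            if fr.solute_pos is not None:
                for j, name in enumerate(fr.solute_names):
                    serial += 1
                    x, y, z = fr.solute_pos[j] / 10.0
                    fh.write(f"{fr.n_waters + 1:5d}{'LIG':<5s}{name[:5]:>5s}"
                             f"{serial % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n")
            if fr.box is not None:
                bx, by, bz = fr.box / 10.0
                fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")
            else:
                fh.write(f"{0.0:10.5f}{0.0:10.5f}{0.0:10.5f}\n")


def write_pdb(frames: list[Frame], path: str | Path) -> None:
    """Write frames as a multi-model PDB (waters as HOH, CRYST1 if boxed)."""
    with open(path, "w") as fh:
        for m, fr in enumerate(frames, start=1):
            if fr.box is not None:
                bx, by, bz = fr.box
                fh.write(f"CRYST1{bx:9.3f}{by:9.3f}{bz:9.3f}"
                         f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
            fh.write(f"MODEL     {m:4d}\n")
            serial = 0
            for i in range(fr.n_waters):
                for name, pos, elem in (("O", fr.o[i], "O"), ("H1", fr.h1[i], "H"),
                                        ("H2", fr.h2[i], "H")):
                    serial += 1
                    fh.write(_pdb_atom(serial, name, "HOH", (i % 9999) + 1, pos, elem,
                                       hetatm=True))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _pdb_atom(serial, name, resname, resid, pos, element, hetatm=False):
    rec = "HETATM" if hetatm else "ATOM  "
    return (f"{rec}{serial % 100000:5d} {name:<4s} {resname:<3s} A{resid:4d}    "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2s}\n")


def write_ring_overlay(rings, frame: Frame, path: str | Path) -> None:
    """Write ring-member oxygens as a PDB overlay, ring id in the residue number."""
    from .rings import WaterRing  # local import to avoid a cycle

    with open(path, "w") as fh:
        fh.write(f"REMARK   ring overlay for frame {frame.index}\n")
        serial = 0
        for rid, ring in enumerate(rings, start=1):
            if isinstance(ring, WaterRing) and ring.frame_index != frame.index:
                raise TrajectoryParseError(
                    f"ring {ring.members} belongs to frame {ring.frame_index}, "
                    f"not {frame.index}"
                )
            for m in ring.members:
                if m < 0 or m >= frame.n_waters:
                    raise TrajectoryParseError(
                        f"ring member index {m} outside frame with "
                        f"{frame.n_waters} waters"
                    )
                serial += 1
                fh.write(_pdb_atom(serial, "O", "TWN", rid, frame.o[m], "O",
                                   hetatm=True))
        fh.write("END\n")


# ---------------------------------------------------------------------------
# ligands
# ---------------------------------------------------------------------------

def read_ligand(
    path: str | Path,
    format: str | None = None,
    regions: str | Path | None = None,
    name: str | None = None,
) -> LigandModel:
    """Read a reference ligand (PDB or SDF) and attach region labels.

    The region annotation is a two-column text file mapping an atom selector
    (1-based index or atom name) to head/linker/tail/L'.  L' atoms are part
    of the linker and additionally flagged.  Unlisted atoms stay unlabeled.
    """
    path = Path(path)
    if not path.exists():
        raise LigandError(f"no such file: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        elements, coords, names = _read_ligand_pdb(path)
    elif fmt == "sdf":
        elements, coords, names = _read_ligand_sdf(path)
    else:
        raise LigandError(f"unsupported ligand format {fmt!r}")
    lig = LigandModel(name or path.stem, elements, coords)
    if regions is not None:
        apply_region_annotation(lig, regions, atom_names=names)
    return lig


def _read_ligand_pdb(path: Path):
    import MDAnalysis as mda

    _prescan_pdb(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as err:
        raise LigandError(f"{path}: could not parse ligand PDB: {err}") from err
    if len(u.atoms) == 0:
        raise LigandError(f"{path}: empty ligand")
    names = [a.name.strip() for a in u.atoms]
    elements = [_element_from_name(n) for n in names]
    return elements, u.atoms.positions.copy(), names


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise LigandError(f"cannot infer element from atom name {name!r}")
    if len(stripped) >= 2 and stripped[:2].capitalize() in ("Cl", "Br"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _read_ligand_sdf(path: Path):
    from rdkit import Chem

    mol = Chem.MolFromMolFile(str(path), removeHs=False, sanitize=False)
    if mol is None:
        raise LigandError(f"{path}: could not parse SDF")
    if mol.GetNumAtoms() == 0:
        raise LigandError(f"{path}: empty ligand")
    conf = mol.GetConformer()
    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    return elements, coords, [f"{e}{i + 1}" for i, e in enumerate(elements)]


def apply_region_annotation(
    lig: LigandModel, regions_path: str | Path, atom_names: list[str] | None = None
) -> None:
    """Attach region labels from a two-column annotation file, in place."""
    regions_path = Path(regions_path)
    if not regions_path.exists():
        raise LigandError(f"no such annotation file: {regions_path}")
    with open(regions_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise LigandError(
                    f"{regions_path}:{lineno}: expected 'selector label', got {raw!r}"
                )
            selector, label = parts
            label_l = label.lower()
            idx = _resolve_atoms(lig, selector, atom_names, regions_path, lineno)
            if label_l in _LPRIME_ALIASES:
                for i in idx:
                    lig.regions[i] = "linker"
                    lig.lprime[i] = True
            elif label_l in REGION_LABELS:
                for i in idx:
                    lig.regions[i] = label_l
            else:
                raise LigandError(
                    f"{regions_path}:{lineno}: unknown region label {label!r}"
                )
    if not lig.labeled_mask.any():
        raise LigandError(f"{regions_path}: annotation labels no atoms")


def _resolve_atoms(lig, selector, atom_names, path, lineno):
    if selector.lstrip("-").isdigit():
        i = int(selector)
        if i < 1 or i > lig.n_atoms:
            raise LigandError(
                f"{path}:{lineno}: atom index {i} out of range 1..{lig.n_atoms}"
            )
        return [i - 1]
    if atom_names is None:
        raise LigandError(f"{path}:{lineno}: atom names unavailable for {selector!r}")
    idx = [k for k, n in enumerate(atom_names) if n == selector]
    if not idx:
        raise LigandError(f"{path}:{lineno}: no atom named {selector!r}")
    return idx


def write_ligand_pdb(lig: LigandModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in range(lig.n_atoms):
            name = f"{lig.elements[i]}{i + 1}"
            fh.write(_pdb_atom(i + 1, name[:4], "LIG", 1, lig.coords[i],
                               lig.elements[i], hetatm=True))
        fh.write("END\n")


def write_region_annotation(lig: LigandModel, path: str | Path) -> None:
    """Write the two-column annotation corresponding to a ligand's labels."""
    with open(path, "w") as fh:
        fh.write("# atom-index  region\n")
        for i, region in enumerate(lig.regions):
            if lig.lprime[i]:
                fh.write(f"{i + 1} lprime\n")
            elif region != "unlabeled":
                fh.write(f"{i + 1} {region}\n")
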