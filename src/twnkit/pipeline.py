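"""End-to-end analysis: frames + ligand + config -> reports and artifacts.

Deterministic for identical inputs and configuration; every effective
parameter is echoed to the run log.  Module errors surface with the name
of the failing stage and partial outputs are removed.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .errors import TwnError
from .io import read_frames, read_ligand, write_ring_overlay
from .occupancy import SiteSpec, occupancy_report
from .rings import rings_to_records
from .shape import (
    SimilarityResult,
    grid_spec_for,
    proximal_rings,
    shape_similarity,
    voxelize_ligand,
    voxelize_twn,
)


@dataclass
class AnalysisResult:
    report: "OccupancyReport"  # noqa: F821 - forward ref for doc purposes
    similarities: dict[str, SimilarityResult]
    output_dir: Path


class StageError(TwnError):
    """Wraps a module error with the name of the pipeline stage."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage
        self.cause = err


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except TwnError as err:
                raise StageError(name, err) from err
        return wrapper
    return deco


def run_analysis(config: RunConfig) -> AnalysisResult:
    """Run the full pipeline described by a validated configuration.

    Reads frames and the annotated reference ligand, restricts waters to
    the binding-site sphere, builds per-frame H-bond graphs, enumerates
    rings, assigns them to ligand regions, and scores shape similarity of
    the ligand-proximal ring ensemble for every scope.  Writes
    ``report.json``, ``report.tsv``, ``rings.tsv``, ``similarity.tsv``
    and ``run_log.txt`` (plus ring overlays when requested).
    """
    inputs = config["inputs"]
    if not inputs["frames"] or not inputs["ligand"]:
        raise StageError("inputs", TwnError("inputs.frames and inputs.ligand are required"))

    out_dir = Path(config["output"]["dir"])
    created = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        return _run(config, out_dir)
    except Exception:
        if created:
            shutil.rmtree(out_dir, ignore_errors=True)
        raise


def _run(config: RunConfig, out_dir: Path) -> AnalysisResult:
    inputs = config["inputs"]
    params = config.potential_params()

    frames = _stage("trajectory_io")(read_frames)(
        inputs["frames"], format=inputs["frames_format"]
    )
    ligand = _stage("trajectory_io")(read_ligand)(
        inputs["ligand"], format=inputs["ligand_format"], regions=inputs["regions"]
    )

    center = config["site"]["center"]
    site = (
        SiteSpec(center=center, radius=config["site"]["radius"])
        if center is not None
        else SiteSpec.around_ligand(ligand, radius=config["site"]["radius"])
    )

    rcfg = config["rings"]
    report, assignments, site_frames = _stage("region_occupancy")(occupancy_report)(
        frames,
        ligand,
        site=site,
        params=params,
        cutoff=config["assignment"]["cutoff_A"],
        lprime_cutoff=config["assignment"]["lprime_cutoff_A"],
        min_size=rcfg["min_size"],
        max_size=rcfg["max_size"],
        chordless=rcfg["chordless"],
        collect_rings=True,
    )

    gcfg = config["grid"]
    all_rings = [a.ring for a in assignments]
    prox = _stage("shape_similarity")(proximal_rings)(
        all_rings, site_frames, ligand, com_cutoff=gcfg["com_cutoff_A"]
    )
    grid = grid_spec_for(ligand, spacing=gcfg["spacing_A"])
    twn_grid = _stage("shape_similarity")(voxelize_twn)(
        prox, site_frames, grid, water_radius=gcfg["water_radius_A"]
    )
    similarities: dict[str, SimilarityResult] = {}
    for scope in ("whole", "head", "linker", "tail", "lprime"):
        if not ligand.scope_mask(scope).any():
            continue
        lig_grid = _stage("shape_similarity")(voxelize_ligand)(
            ligand, scope=scope, grid=grid
        )
        similarities[scope] = _stage("shape_similarity")(shape_similarity)(
            lig_grid, twn_grid, mode=gcfg["mode"], scope=scope,
            n_rings_used=len(prox),
        )

    _write_outputs(config, out_dir, report, assignments, site_frames,
                   similarities)
    return AnalysisResult(report=report, similarities=similarities,
                          output_dir=out_dir)


def _write_outputs(config, out_dir, report, assignments, site_frames,
                   similarities):
    report.to_json(out_dir / "report.json")

    rows = []
    for region, count in report.counts.items():
        rows.append({"region": region, "rings": count,
                     "percent": round(report.percentages[region], 4)})
    pd.DataFrame(rows).to_csv(out_dir / "report.tsv", sep="\t", index=False)

    ring_records = rings_to_records([a.ring for a in assignments], site_frames)
    for rec, a in zip(ring_records, assignments):
        rec["region"] = a.region
        rec["lprime"] = a.is_lprime
        rec["distance"] = round(a.distance, 4)
    pd.DataFrame(
        ring_records,
        columns=["frame", "size", "members", "residues", "center_x",
                 "center_y", "center_z", "region", "lprime", "distance"],
    ).to_csv(out_dir / "rings.tsv", sep="\t", index=False)

    sim_rows = [
        {"scope": s.scope, "percent": round(s.percent, 4), "mode": s.mode,
         "n_rings_used": s.n_rings_used}
        for s in similarities.values()
    ]
    pd.DataFrame(sim_rows).to_csv(out_dir / "similarity.tsv", sep="\t",
                                  index=False)

    if config["output"]["overlays"]:
        overlay_dir = out_dir / "overlays"
        overlay_dir.mkdir(exist_ok=True)
        by_frame: dict[int, list] = {}
        for a in assignments:
            by_frame.setdefault(a.ring.frame_index, []).append(a.ring)
        for fi, rings in sorted(by_frame.items()):
            write_ring_overlay(rings, site_frames[fi],
                               overlay_dir / f"frame_{fi:05d}.pdb")

    with open(out_dir / "run_log.txt", "w") as fh:
        fh.write(f"twnkit {__version__}\n")
        for key, value in sorted(config.flat().items()):
            fh.write(f"{key} = {json.dumps(value)}\n")
        fh.write(f"frames_analyzed = {report.n_frames}\n")
        fh.write(f"rings_assigned = {report.n_assigned}\n")
        fh.write(f"rings_unassigned = {report.n_unassigned}\n")
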