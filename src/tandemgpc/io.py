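"""File I/O: design/schedule YAML, GenBank/FASTA/CSV export, run manifests."""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .circuit import CircuitDesign, design_from_dict, design_to_dict
from .compiler import (
    DELETED, CompiledConstruct, enumerate_stages, scar_peptide, to_seqrecord,
)
from .dynamics import (
    KineticParams, LigandSchedule, Population, Trajectory,
)


# --- designs and schedules -------------------------------------------------

def load_design(path) -> CircuitDesign:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: design YAML must be a mapping")
    return design_from_dict(data)


def save_design(design: CircuitDesign, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design_to_dict(design), fh, sort_keys=False)


def design_hash(design: CircuitDesign) -> str:
    blob = json.dumps(design_to_dict(design), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def load_schedule(path) -> LigandSchedule:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    windows = [(w["ligand"], w["start_h"], w["end_h"]) for w in data["windows"]]
    horizon = data.get("horizon_h") or max(w[2] for w in windows)
    return LigandSchedule(tuple(windows), horizon=float(horizon))


def save_schedule(schedule: LigandSchedule, path) -> None:
    data = {
        "windows": [{"ligand": l, "start_h": a, "end_h": b}
                    for l, a, b in schedule.windows],
        "horizon_h": schedule.horizon,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# --- stage exports ----------------------------------------------------------

def write_stage_files(design: CircuitDesign, out_dir) -> list[str]:
    """GenBank + FASTA per stage plus a stage summary table.

    Returns the list of files written (relative names).
    """
    from Bio import SeqIO

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    rows = []
    for construct in enumerate_stages(design):
        stage = construct.stage
        tag = "deleted" if stage == DELETED else f"stage{stage}"
        rec = to_seqrecord(construct)
        for ext, fmt in (("gb", "genbank"), ("fasta", "fasta")):
            fn = f"{design.name}_{tag}.{ext}"
            SeqIO.write(rec, out_dir / fn, fmt)
            written.append(fn)
        if stage == DELETED:
            frame_ok = ""
        elif design.version == "v2":
            _, frame_ok = scar_peptide(design, stage)
        else:
            frame_ok = ""
        rows.append({
            "stage": stage,
            "expressed_payloads": "+".join(sorted(construct.expressed)),
            "scar_length_bp": len(construct.scar.cumulative),
            "frame_ok": frame_ok,
            "length_bp": len(construct.sequence),
        })
    table = f"{design.name}_stages.csv"
    pd.DataFrame(rows).to_csv(out_dir / table, index=False)
    written.append(table)
    return written


# --- trajectories and populations -------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False, float_format="%.10g")


def save_population(pop: Population, path) -> None:
    np.savez_compressed(
        path, cell_of_copy=pop.cell_of_copy, entry_times=pop.entry_times,
        deleted_time=pop.deleted_time, alive=pop.alive,
        seed=-1 if pop.seed is None else pop.seed)


def load_population(path, design: CircuitDesign,
                    params: KineticParams) -> Population:
    z = np.load(path)
    seed = int(z["seed"])
    return Population(
        design=design, params=params, cell_of_copy=z["cell_of_copy"],
        entry_times=z["entry_times"], deleted_time=z["deleted_time"],
        alive=z["alive"], seed=None if seed < 0 else seed)


# --- run manifest ------------------------------------------------------------

def write_manifest(path, *, design: CircuitDesign, params: KineticParams,
                   schedule: LigandSchedule, seed: int, n: int,
                   outputs: list[str], extra: dict | None = None) -> dict:
    manifest = {
        "tool": "tandemgpc",
        "version": __version__,
        "design_name": design.name,
        "design_sha256": design_hash(design),
        "params": dataclasses.asdict(params),
        "schedule": {
            "windows": [list(w) for w in schedule.windows],
            "horizon_h": schedule.horizon,
        },
        "seed": seed,
        "n_cells": n,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": outputs,
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
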