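"""Trajectory input, the plain-text snapshot dialect, and report output.

Two input paths are supported:

* a plain-text snapshot dialect — one line per water per frame,
  ``frame_index molecule_id Ox Oy Oz H1x H1y H1z H2x H2y H2z`` in Å,
  ``#`` comments — which keeps the whole pipeline runnable without any
  binary trajectory files;
* standard topology + coordinate trajectories (PDB topology with
  DCD/XTC-style coordinates) through MDAnalysis, behind a thin adapter.

Solute nonbonded parameters come from a simple per-atom table
(columns: name, x, y, z, charge, sigma, epsilon); no force-field file
parsing.  Reports are written as CSV (4 decimals) and JSON (full
precision).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .energetics import NonbondedSite
from .geometry import WaterAtoms, WaterPose, pose_from_atoms
from .sites import HydrationSite

__all__ = [
    "write_snapshots",
    "read_snapshots",
    "frames_to_poses",
    "load_trajectory",
    "read_solute_table",
    "read_sites_config",
    "write_report",
]

WATER_RESNAMES = ("HOH", "TIP", "TIP3", "TIP4", "WAT", "SOL", "SPC")


class FormatError(ValueError):
    """Malformed trajectory or table input."""


def write_snapshots(path, frames: list[dict[str, WaterAtoms]],
                    header: str = "") -> None:
    """Write frames of named waters in the snapshot dialect.

    ``frames[f]`` maps molecule id -> :class:`WaterAtoms`.
    """
    with open(path, "w") as fh:
        fh.write("# hydrosite snapshot dialect: frame mol Ox Oy Oz H1x H1y H1z H2x H2y H2z\n")
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        for f_idx, frame in enumerate(frames):
            for mol_id, w in frame.items():
                coords = np.concatenate([w.oxygen, w.hydrogen1, w.hydrogen2])
                fh.write(f"{f_idx} {mol_id} " + " ".join(f"{c:.6f}" for c in coords) + "\n")


def read_snapshots(path) -> list[dict[str, WaterAtoms]]:
    """Read a snapshot-dialect file back into frames of named waters.

    Frames must be contiguous and sorted; a molecule id may appear at
    most once per frame.
    """
    frames: list[dict[str, WaterAtoms]] = []
    last = -1
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 11:
                raise FormatError(f"{path}:{ln}: expected 11 fields, got {len(parts)}")
            f_idx = int(parts[0])
            mol = parts[1]
            xyz = np.array([float(v) for v in parts[2:]], dtype=float)
            if f_idx == last + 1:
                frames.append({})
                last = f_idx
            elif f_idx != last:
                raise FormatError(f"{path}:{ln}: frames not contiguous/sorted ({f_idx} after {last})")
            if mol in frames[-1]:
                raise FormatError(f"{path}:{ln}: duplicate molecule id {mol} in frame {f_idx}")
            frames[-1][mol] = WaterAtoms(xyz[0:3], xyz[3:6], xyz[6:9])
    return frames


def frames_to_poses(frames: list[dict[str, WaterAtoms]]) -> list[list[WaterPose]]:
    """Convert frames of raw water atoms into per-frame pose lists."""
    return [[pose_from_atoms(w, f_idx) for w in frame.values()]
            for f_idx, frame in enumerate(frames)]


def load_trajectory(topology, coords=None,
                    water_resnames=WATER_RESNAMES):
    """Load waters (and any non-water atoms) from standard files.

    ``topology`` is a PDB; ``coords`` an optional DCD/XTC-style
    trajectory (a snapshot-dialect path is also accepted and detected
    by extension ``.snap``/``.txt``).  Returns ``(frames, solute)``
    where ``frames`` is a list of per-frame dicts of
    :class:`WaterAtoms` and ``solute`` an (n_atoms, 3) coordinate array
    of the fixed non-water atoms (first frame).
    """
    top = Path(topology)
    if top.suffix in (".snap", ".txt"):
        return read_snapshots(top), np.empty((0, 3))
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading PDB/DCD/XTC requires MDAnalysis; "
                          "use the snapshot dialect otherwise") from exc
    uni = mda.Universe(str(top)) if coords is None else mda.Universe(str(top), str(coords))
    waters = uni.select_atoms("resname " + " ".join(water_resnames))
    solute_atoms = uni.select_atoms("not resname " + " ".join(water_resnames))
    residues = waters.residues
    frames = []
    for _ in uni.trajectory:
        frame: dict[str, WaterAtoms] = {}
        for res in residues:
            names = [a.name.upper() for a in res.atoms]
            opos = hpos = None
            o_idx = [i for i, n in enumerate(names) if n.startswith("O")]
            h_idx = [i for i, n in enumerate(names) if n.startswith("H")]
            if not o_idx or len(h_idx) < 2:
                raise FormatError(
                    f"water residue {res.resid} lacks O/H/H atoms (names {names})")
            pos = res.atoms.positions
            frame[f"{res.resname}{res.resid}"] = WaterAtoms(
                pos[o_idx[0]], pos[h_idx[0]], pos[h_idx[1]])
        frames.append(frame)
    solute = solute_atoms.positions.copy() if len(solute_atoms) else np.empty((0, 3))
    return frames, solute


def read_solute_table(path) -> list[NonbondedSite]:
    """Read per-atom solute parameters: name, x, y, z, charge, sigma, epsilon."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = {"x", "y", "z", "charge", "sigma", "epsilon"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"solute table missing columns: {sorted(missing)}")
    return [NonbondedSite(np.array([r.x, r.y, r.z]), float(r.charge),
                          float(r.sigma), float(r.epsilon))
            for r in df.itertuples()]


def read_sites_config(path) -> list[HydrationSite]:
    """Read hydration-site definitions: site_id, x, y, z[, radius]."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if not {"site_id", "x", "y", "z"} <= set(df.columns):
        raise FormatError("sites config needs columns site_id, x, y, z[, radius]")
    out = []
    for r in df.itertuples():
        kwargs = {"radius": float(r.radius)} if "radius" in df.columns else {}
        out.append(HydrationSite(str(r.site_id), np.array([r.x, r.y, r.z]), **kwargs))
    return out


def sites_from_pdb_waters(pdb_path, radius: float = 1.2) -> list[HydrationSite]:
    """Use a PDB's water oxygen records as hydration-site centres."""
    frames, _ = load_trajectory(pdb_path)
    if not frames:
        raise FormatError("no frames in PDB")
    return [HydrationSite(mol, w.oxygen, radius=radius, source_label=mol)
            for mol, w in frames[0].items()]


def write_report(outdir, name: str, payload: dict) -> tuple[Path, Path]:
    """Write a report as full-precision JSON and 4-decimal CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    jpath = outdir / f"{name}.json"
    with open(jpath, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
    cpath = outdir / f"{name}.csv"
    rows = payload.get("rows")
    if rows:
        pd.DataFrame(rows).round(4).to_csv(cpath, index=False)
    else:
        flat = {k: v for k, v in payload.items() if np.isscalar(v)}
        pd.DataFrame([flat]).round(4).to_csv(cpath, index=False)
    return jpath, cpath
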