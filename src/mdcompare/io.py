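"""Readers and writers: PDB structures/trajectories, XYZ streams, results tables.

PDB parsing and formatting are delegated to biotite; this module converts
between biotite's ``AtomArrayStack`` and the package's :class:`Trajectory`.
Multi-model PDB files become multi-frame trajectories (frame times at a
fixed stride, default 1 ps, the usual snapshot spacing).
"""

from __future__ import annotations

import json
import os
from typing import Optional

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .core import (Atom, Frame, Topology, Trajectory, WATER_RESNAMES,
                   infer_element, vdw_radius_of)

__all__ = ["read_pdb", "write_pdb", "read_xyz", "write_xyz",
           "write_table", "read_table"]


def _prevalidate_pdb(path: str) -> None:
    # biotite's errors do not carry line numbers; do a cheap coordinate-field
    # scan first so malformed records are reported with their line.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise ValueError(
                        f"{path}: truncated coordinate record at line {lineno}")
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except ValueError:
                    raise ValueError(
                        f"{path}: unparseable coordinates at line {lineno}: "
                        f"{line.rstrip()!r}") from None
                if line[26] != " ":
                    raise ValueError(
                        f"{path}: insertion code {line[26]!r} at line "
                        f"{lineno}; insertion codes are not supported")


def read_pdb(path: str, dt: float = 1.0,
             water_resnames=WATER_RESNAMES,
             radii: Optional[dict] = None) -> Trajectory:
    """Read a (possibly multi-model) PDB file into a :class:`Trajectory`.

    One frame per MODEL record (a single frame if there are none); altloc
    conflicts are resolved to the highest occupancy; blank element columns
    are inferred from the atom name; van der Waals radii come from the
    bundled Bondi table unless ``radii`` overrides it.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    _prevalidate_pdb(path)
    pdb = PDBFile.read(path)
    try:
        stack = pdb.get_structure(model=None, altloc="occupancy",
                                  extra_fields=["b_factor"])
    except Exception as exc:  # models of differing atom counts, bad records
        raise ValueError(f"{path}: {exc}") from exc
    if stack.array_length() == 0:
        raise ValueError(f"{path}: no atoms found")

    first = stack[0]
    atoms = []
    for i in range(first.array_length()):
        name = str(first.atom_name[i])
        resname = str(first.res_name[i])
        element = str(first.element[i]).strip().upper()
        if not element:
            element = infer_element(name, resname)
        atoms.append(Atom(
            serial=i + 1,
            name=name,
            element=element,
            resname=resname,
            resid=int(first.res_id[i]),
            chain=str(first.chain_id[i]),
            bfactor_exp=float(first.b_factor[i]),
            vdw_radius=vdw_radius_of(element, radii),
        ))
    topology = Topology(atoms, water_resnames=water_resnames)
    # the text fields carry exactly 3 decimals; rounding removes the float32
    # noise biotite's parser introduces, recovering the printed values
    coords = np.round(np.asarray(stack.coord, dtype=np.float64), 3)
    times = np.arange(coords.shape[0], dtype=np.float64) * float(dt)
    return Trajectory(topology, coords, times)


def _to_stack(traj: Trajectory) -> struc.AtomArrayStack:
    top = traj.topology
    n = top.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n)
    # pre-round to the PDB's 3 decimals so the float32 conversion inside
    # biotite cannot flip the printed last digit
    stack.coord = np.round(traj.coords, 3).astype(np.float32)
    stack.chain_id = np.array([str(c) for c in top.chains], dtype="U4")
    stack.res_id = top.resids.astype(int)
    stack.res_name = np.array([str(r) for r in top.resnames], dtype="U5")
    stack.atom_name = np.array([str(a) for a in top.names], dtype="U6")
    stack.element = np.array([str(e) for e in top.elements], dtype="U2")
    stack.hetero = top.water_mask
    bf = np.nan_to_num(top.bfactors_exp, nan=0.0)
    stack.set_annotation("b_factor", np.repeat(bf[None, :], 1, axis=0)[0])
    return stack


def write_pdb(traj: Trajectory, path: str) -> None:
    """Write a trajectory as a (multi-)MODEL PDB file.

    Coordinates round-trip through :func:`read_pdb` to PDB precision
    (three decimals, 5e-4 A).
    """
    pdb = PDBFile()
    pdb.set_structure(_to_stack(traj))
    pdb.write(path)


def read_xyz(path: str, topology: Topology, dt: float = 1.0) -> Trajectory:
    """Read a plain multi-frame XYZ coordinate stream onto a known topology.

    Each block: an atom-count line, a comment line, then ``count`` lines of
    ``symbol x y z``.  The count must match the topology in every frame.
    """
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame_index = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            count = int(lines[pos].split()[0])
        except ValueError:
            raise ValueError(f"{path}: expected atom count at line {pos + 1}")
        if count != topology.n_atoms:
            raise ValueError(
                f"{path}: frame {frame_index} has {count} atoms, topology "
                f"has {topology.n_atoms}")
        block = lines[pos + 2: pos + 2 + count]
        if len(block) < count:
            raise ValueError(f"{path}: truncated frame {frame_index}")
        xyz = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        frames.append(xyz)
        pos += 2 + count
        frame_index += 1
    if not frames:
        raise ValueError(f"{path}: no frames found")
    coords = np.stack(frames)
    times = np.arange(coords.shape[0], dtype=np.float64) * float(dt)
    return Trajectory(topology, coords, times)


def write_xyz(traj: Trajectory, path: str) -> None:
    top = traj.topology
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{top.n_atoms}\n")
            fh.write(f"t= {traj.times[f]:.3f} ps\n")
            for i in range(top.n_atoms):
                x, y, z = traj.coords[f, i]
                fh.write(f"{top.elements[i]:<2s} {x:14.6f} {y:14.6f} "
                         f"{z:14.6f}\n")


def write_table(df, path: str, json_mirror: bool = True) -> None:
    """Write a results DataFrame as TSV with a one-line header + JSON mirror."""
    df.to_csv(path, sep="\t", index=False)
    if json_mirror:
        mirror = os.path.splitext(path)[0] + ".json"
        with open(mirror, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1, default=str)


def read_table(path: str):
    import pandas as pd
    return pd.read_csv(path, sep="\t")
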