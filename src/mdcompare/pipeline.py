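"""End-to-end comparative workflow over two systems.

A single config (YAML or dict) names both systems' trajectories, their
chain assignments (never guessed), optional region selections and energy
tables, and every threshold.  Stages run in dependency order; a failure
in one stage is recorded and does not abort independent stages.  The
report is deterministic for fixed inputs: no timestamps, sorted keys,
and a provenance block with config and input digests.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .core import Selection, Trajectory, select
from .io import read_pdb, write_table
from . import contacts as contacts_mod
from . import energetics as energetics_mod
from . import fluctuation as fluct_mod
from . import interactions as inter_mod
from . import landscape as landscape_mod
from . import surfaces as surfaces_mod

__all__ = ["DEFAULT_THRESHOLDS", "run", "load_config"]

ALL_STAGES = ("fluctuation", "contacts", "interactions", "surfaces",
              "landscape", "energetics")

DEFAULT_THRESHOLDS = {
    "contact_cutoff": 4.5,        # A, residue contact
    "hbond_dist": 3.5,            # A, acceptor...hydrogen
    "hbond_angle": 135.0,         # degrees, acceptor-hydrogen-donor
    "saltbridge_cutoff": 4.0,     # A, O...N
    "water_shell": 4.0,           # A, interface-water census
    "cluster_threshold": 1.7,     # A, RMSD
    "temperature": 300.0,         # K
    "probe_radius": 1.4,          # A
    "sasa_points": 960,
    "fel_bins": 50,
}


def load_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _sel(text) -> Selection:
    return Selection.parse(text) if isinstance(text, str) else text


def run(config, outdir: Optional[str] = None) -> dict:
    """Run the comparative pipeline; returns the report dict.

    ``config`` is a dict or a YAML path.  Required per system: ``name``,
    ``trajectory`` (multi-model PDB) or a ``Trajectory`` object under
    ``trajectory_obj``, and ``chains`` with ``receptor`` and ``partner``
    entries.  Optional: ``region`` selection for the water census,
    ``energy_table`` TSV.  Top-level: ``stages``, ``thresholds``,
    ``stride``, ``window`` (analysis frame range), ``outdir``.
    """
    if isinstance(config, (str, os.PathLike)):
        config = load_config(str(config))
    config = dict(config)
    systems = config.get("systems", [])
    if not systems:
        raise ValueError("config must name at least one system")
    for sy in systems:
        ch = sy.get("chains") or {}
        if "receptor" not in ch or "partner" not in ch:
            raise ValueError(
                f"system {sy.get('name', '?')!r}: explicit chain assignments "
                "(receptor, partner) are required and are never guessed")
    thresholds = {**DEFAULT_THRESHOLDS, **(config.get("thresholds") or {})}
    stages = tuple(config.get("stages") or ALL_STAGES)
    stride = int(config.get("stride", 1))
    outdir = outdir or config.get("outdir")
    if outdir:
        os.makedirs(outdir, exist_ok=True)

    report: dict = {"systems": {}, "deltas": {}, "errors": {},
                    "thresholds": thresholds, "stages": list(stages)}
    energy_tables = {}

    for sy in systems:
        name = sy["name"]
        block: dict = {}
        errors: dict = {}
        if "trajectory_obj" in sy:
            traj = sy["trajectory_obj"]
            traj_digest = "in-memory"
        else:
            traj = read_pdb(sy["trajectory"])
            traj_digest = _digest(sy["trajectory"])
        window = config.get("window")
        if window:
            traj = traj.slice_frames(int(window[0]), int(window[1]))
        rec = Selection(chains=frozenset([sy["chains"]["receptor"]]))
        par = Selection(chains=frozenset([sy["chains"]["partner"]]))
        both = Selection(chains=frozenset([sy["chains"]["receptor"],
                                           sy["chains"]["partner"]]))
        ca = both & Selection(calpha_only=True)
        region = _sel(sy.get("region")) if sy.get("region") else rec

        def stage(key, fn):
            if key not in stages:
                return
            try:
                block[key] = fn()
            except Exception as exc:
                errors[key] = f"{type(exc).__name__}: {exc}"

        def do_fluct():
            prof = fluct_mod.rmsf(traj, ca)
            series = fluct_mod.rmsd_series(traj, ca, traj.frame(0))
            rg = fluct_mod.radius_of_gyration(traj, both)
            if outdir:
                import pandas as pd
                write_table(pd.DataFrame({
                    "residue": prof.residue_labels,
                    "rmsf_A": prof.rmsf,
                    "bfactor_A2": prof.bfactor}),
                    os.path.join(outdir, f"{_slug(name)}_rmsf.tsv"))
            return {
                "rmsd_mean_A": float(series.mean()),
                "rmsd_sd_A": float(series.std()),
                "rmsf_mean_A": float(prof.rmsf.mean()),
                "rmsf_max_A": float(prof.rmsf.max()),
                "rg_mean_A": float(rg.mean()),
                "n_residues": len(prof.residue_labels),
            }

        def do_contacts():
            first = contacts_mod.contact_map(
                traj.frame(0), traj.topology, rec, par,
                cutoff=thresholds["contact_cutoff"])
            last = contacts_mod.contact_map(
                traj.frame(traj.n_frames - 1), traj.topology, rec, par,
                cutoff=thresholds["contact_cutoff"])
            comp = contacts_mod.compare_contacts(first, last)
            return {
                "n_initial": comp.n_initial, "n_final": comp.n_final,
                "n_common": comp.n_common,
                "n_specific_initial": comp.n_specific_initial,
                "n_specific_final": comp.n_specific_final,
                "similarity_pct": 100.0 * comp.similarity,
                "reduction_rate_pct": 100.0 * comp.reduction_rate,
            }

        def do_interactions():
            out = {}
            hbonds = []
            for dn, ac in ((rec, par), (par, rec)):
                try:
                    hbonds += inter_mod.detect_hbonds(
                        traj, dn, ac, dist_cutoff=thresholds["hbond_dist"],
                        angle_cutoff=thresholds["hbond_angle"], stride=stride)
                except ValueError:
                    pass  # one side may carry no donor hydrogens
            out["hbonds"] = [
                {"donor": hb.labels[0], "acceptor": hb.labels[2],
                 "occupancy": round(hb.occupancy, 4)}
                for hb in hbonds]
            out["hbonds_over_40pct"] = sum(
                1 for hb in hbonds if hb.occupancy > 0.40)
            sbs = inter_mod.detect_salt_bridges(
                traj, rec, par, cutoff=thresholds["saltbridge_cutoff"],
                stride=stride)
            out["salt_bridges"] = [
                {"pair": list(sb.labels), "class": sb.bridge_class,
                 "occupancy": round(sb.occupancy, 4)} for sb in sbs]
            counts, mean, _ = inter_mod.interface_water_count(
                traj, region, cutoff=thresholds["water_shell"],
                stride=stride)
            out["interface_water_mean"] = mean
            try:
                bridges, relay = inter_mod.detect_water_bridges(
                    traj, rec, par, stride=stride,
                    dist_cutoff=thresholds["hbond_dist"],
                    angle_cutoff=thresholds["hbond_angle"])
                out["water_bridges"] = [
                    {"water": f"{wb.water[0]}:{wb.water[1]}",
                     "partners": [wb.labels[1], wb.labels[2]],
                     "occupancy": round(wb.occupancy, 4)} for wb in bridges]
                out["water_relay"] = {f"{a}|{b}": round(v, 4)
                                      for (a, b), v in relay.items()}
            except ValueError:
                out["water_bridges"] = []
                out["water_relay"] = {}
            return out

        def do_surfaces():
            ba = surfaces_mod.buried_area_series(
                traj, rec, par, probe=thresholds["probe_radius"],
                n_points=int(thresholds["sasa_points"]),
                stride=max(stride, max(1, traj.n_frames // 10)))
            return {"buried_mean_A2": ba.mean, "buried_sd_A2": ba.sd,
                    "s_a_A2": ba.s_a, "s_b_A2": ba.s_b, "s_ab_A2": ba.s_ab}

        def do_landscape():
            modes = landscape_mod.pca(traj, ca)
            fel = landscape_mod.free_energy_landscape(
                modes, temperature=thresholds["temperature"],
                n_bins=int(thresholds["fel_bins"]))
            cl = landscape_mod.cluster(
                traj, ca, threshold=thresholds["cluster_threshold"],
                stride=stride)
            evr = modes.explained_variance_ratio()
            return {
                "pc1_variance_pct": float(100 * evr[0]),
                "pc2_variance_pct": float(100 * evr[1]),
                "n_basins": fel.n_basins,
                "n_clusters": cl.n_clusters,
                "top_cluster_population": float(cl.populations.max()),
            }

        def do_energetics():
            if not sy.get("energy_table"):
                raise ValueError("no energy table supplied")
            tables = energetics_mod.energy_tables_from_tsv(sy["energy_table"])
            t = tables[0]
            energy_tables[name] = t
            return {
                "dh": t.dh, "t_ds": t.t_ds, "dg_bind": t.dg_bind,
                "polar": t.polar, "nonpolar": t.nonpolar,
                "favorability": t.favorability(),
                "dg_exp": t.dg_exp if t.dg_exp is not None else "n/a",
            }

        stage("fluctuation", do_fluct)
        stage("contacts", do_contacts)
        stage("interactions", do_interactions)
        stage("surfaces", do_surfaces)
        stage("landscape", do_landscape)
        stage("energetics", do_energetics)

        report["systems"][name] = block
        if errors:
            report["errors"][name] = errors
        block["provenance_digest"] = traj_digest

    if len(systems) >= 2 and len(energy_tables) >= 2:
        names = [sy["name"] for sy in systems[:2]]
        report["deltas"]["energy"] = energetics_mod.compare_systems(
            energy_tables[names[0]], energy_tables[names[1]])
    if len(systems) >= 2:
        deltas = {}
        a, b = (report["systems"][sy["name"]] for sy in systems[:2])
        for key in ("contacts", "surfaces", "fluctuation"):
            if key in a and key in b:
                deltas[key] = {
                    k: a[key][k] - b[key][k]
                    for k in a[key]
                    if isinstance(a[key][k], (int, float))
                    and isinstance(b[key].get(k), (int, float))}
        report["deltas"].update(deltas)

    report["provenance"] = {
        "version": __version__,
        "config_digest": hashlib.sha256(
            json.dumps(_jsonable(config), sort_keys=True, default=str)
            .encode()).hexdigest()[:16],
        "thresholds": thresholds,
    }

    if outdir:
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
        with open(os.path.join(outdir, "report.txt"), "w") as fh:
            fh.write(_render_text(report))
    return report


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Trajectory):
        return f"<trajectory {obj.n_frames}x{obj.n_atoms}>"
    return obj


def _render_text(report: dict) -> str:
    lines = ["mdcompare comparative report", "=" * 32]
    for name, block in report["systems"].items():
        lines.append(f"\n[{name}]")
        for stage, vals in block.items():
            if not isinstance(vals, dict):
                continue
            lines.append(f"  {stage}:")
            for k, v in vals.items():
                if isinstance(v, float):
                    lines.append(f"    {k:28s} {v:12.4f}")
                elif isinstance(v, (int, str)):
                    lines.append(f"    {k:28s} {v}")
    if report.get("deltas"):
        lines.append("\n[cross-system deltas]")
        for k, v in report["deltas"].items():
            lines.append(f"  {k}: {json.dumps(_jsonable(v), sort_keys=True)}")
    if report.get("errors"):
        lines.append("\n[stage errors]")
        for name, errs in report["errors"].items():
            for st, msg in errs.items():
                lines.append(f"  {name}/{st}: {msg}")
    return "\n".join(lines) + "\n"
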