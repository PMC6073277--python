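"""Binding-free-energy assembly and per-residue decomposition bookkeeping.

The MM/PBSA end-point scheme splits binding into
``dG_bind = dH - T dS`` with the enthalpy assembled from four component
means: gas-phase van der Waals (E_VDW) and electrostatics (E_ELE), polar
solvation (G_PBELE) and nonpolar solvation (G_PBSUR), all in kcal/mol.
This module performs only the arithmetic assembly, polar/nonpolar
grouping (polar = E_ELE + G_PBELE, nonpolar = E_VDW + G_PBSUR;
negative values favour binding) and key-residue filtering — the solver
outputs arrive as tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

__all__ = ["EnergyTable", "ResidueEnergyRow", "assemble", "key_residues",
           "compare_systems", "energy_tables_from_tsv",
           "residue_rows_from_tsv"]

_COMPONENT_TOL = 0.02   # kcal/mol slack for published rounding


@dataclass
class EnergyTable:
    name: str = ""
    e_vdw: Optional[float] = None
    e_ele: Optional[float] = None
    g_pbele: Optional[float] = None
    g_pbsur: Optional[float] = None
    t_ds: Optional[float] = None       # T * dS, kcal/mol
    dh: Optional[float] = None
    dg_bind: Optional[float] = None
    dg_exp: Optional[float] = None
    sd: dict = field(default_factory=dict)

    @property
    def components_complete(self) -> bool:
        return None not in (self.e_vdw, self.e_ele, self.g_pbele,
                            self.g_pbsur)

    @property
    def polar(self) -> Optional[float]:
        if self.e_ele is None or self.g_pbele is None:
            return None
        return self.e_ele + self.g_pbele

    @property
    def nonpolar(self) -> Optional[float]:
        if self.e_vdw is None or self.g_pbsur is None:
            return None
        return self.e_vdw + self.g_pbsur

    def favorability(self) -> dict:
        out = {}
        for k, v in (("polar", self.polar), ("nonpolar", self.nonpolar)):
            if v is not None:
                out[k] = "favorable" if v < 0 else "unfavorable"
        return out


@dataclass(frozen=True)
class ResidueEnergyRow:
    label: str
    total: float                       # kcal/mol
    backbone: Optional[float] = None
    sidechain: Optional[float] = None

    def __post_init__(self):
        if self.backbone is not None and self.sidechain is not None:
            if abs(self.backbone + self.sidechain - self.total) > 1e-6:
                raise ValueError(
                    f"{self.label}: backbone + side chain != total")


def assemble(name: str = "", e_vdw: Optional[float] = None,
             e_ele: Optional[float] = None, g_pbele: Optional[float] = None,
             g_pbsur: Optional[float] = None, t_ds: Optional[float] = None,
             dh: Optional[float] = None, dg_exp: Optional[float] = None,
             sd: Optional[dict] = None) -> EnergyTable:
    """Assemble dG_bind = dH - T dS, deriving dH from components if given.

    Either ``dh`` or all four components must be provided along with
    ``t_ds``.  If both are given they must agree within 0.02 kcal/mol
    (published-rounding slack).
    """
    table = EnergyTable(name=name, e_vdw=e_vdw, e_ele=e_ele,
                        g_pbele=g_pbele, g_pbsur=g_pbsur, t_ds=t_ds,
                        dh=dh, dg_exp=dg_exp, sd=sd or {})
    if table.components_complete:
        comp_dh = e_vdw + e_ele + g_pbele + g_pbsur
        if dh is not None and abs(dh - comp_dh) > _COMPONENT_TOL:
            raise ValueError(
                f"{name}: stated dH {dh} and component sum {comp_dh:.4f} "
                f"disagree by more than {_COMPONENT_TOL} kcal/mol")
        table.dh = comp_dh if dh is None else dh
    elif dh is None:
        raise ValueError(f"{name}: need dH or all four components")
    if t_ds is None:
        raise ValueError(f"{name}: need the entropy term T*dS")
    table.dg_bind = table.dh - t_ds
    return table


def key_residues(rows: list[ResidueEnergyRow], cutoff: float = -1.0
                 ) -> list[ResidueEnergyRow]:
    """Residues contributing less than ``cutoff`` kcal/mol (default -1),
    sorted most-favourable first."""
    return sorted((r for r in rows if r.total < cutoff),
                  key=lambda r: r.total)


def compare_systems(a: EnergyTable, b: EnergyTable) -> dict:
    """Cross-system differences (a minus b) with polar/nonpolar attribution."""
    if a.dg_bind is None or b.dg_bind is None:
        raise ValueError("both tables must be assembled first")

    def diff(x, y):
        return None if (x is None or y is None) else x - y

    return {
        "systems": (a.name, b.name),
        "ddg_bind": a.dg_bind - b.dg_bind,
        "ddh": diff(a.dh, b.dh),
        "dtds": diff(a.t_ds, b.t_ds),
        "d_e_vdw": diff(a.e_vdw, b.e_vdw),
        "d_e_ele": diff(a.e_ele, b.e_ele),
        "d_g_pbele": diff(a.g_pbele, b.g_pbele),
        "d_g_pbsur": diff(a.g_pbsur, b.g_pbsur),
        "d_polar": diff(a.polar, b.polar),
        "d_nonpolar": diff(a.nonpolar, b.nonpolar),
        "favors": a.name if a.dg_bind < b.dg_bind else b.name,
    }


_COLMAP = {"e_vdw": "E_VDW", "e_ele": "E_ELE", "g_pbele": "G_PBELE",
           "g_pbsur": "G_PBSUR", "t_ds": "TDS", "dh": "DH",
           "dg_exp": "DG_EXP"}


def energy_tables_from_tsv(path: str) -> list[EnergyTable]:
    """Read per-system component tables from TSV.

    Columns: ``system`` plus any of E_VDW, E_ELE, G_PBELE, G_PBSUR, TDS,
    DH, DG_EXP; optional ``<col>_SD`` columns carry standard deviations.
    """
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        sd = {}
        for attr, col in _COLMAP.items():
            if col in df.columns and pd.notna(row[col]):
                kwargs[attr] = float(row[col])
            sd_col = f"{col}_SD"
            if sd_col in df.columns and pd.notna(row[sd_col]):
                sd[col] = float(row[sd_col])
        out.append(assemble(name=str(row["system"]), sd=sd, **kwargs))
    return out


def residue_rows_from_tsv(path: str) -> list[ResidueEnergyRow]:
    """Read per-residue decomposition rows (residue, total[, backbone,
    sidechain]) from TSV."""
    df = pd.read_csv(path, sep="\t")
    rows = []
    for _, r in df.iterrows():
        rows.append(ResidueEnergyRow(
            label=str(r["residue"]), total=float(r["total"]),
            backbone=float(r["backbone"]) if "backbone" in df.columns
            and pd.notna(r["backbone"]) else None,
            sidechain=float(r["sidechain"]) if "sidechain" in df.columns
            and pd.notna(r["sidechain"]) else None))
    return rows
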