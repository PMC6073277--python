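"""Solvent-accessible surface area (Shrake-Rupley) and buried interface area.

SASA is the area traced by the centre of a probe sphere (default radius
1.4 A, a water molecule) rolling over the van der Waals surface.  Each
atom's expanded sphere (r_vdw + probe) is covered with a deterministic
Fibonacci lattice of quasi-uniform points; the accessible fraction is the
fraction of points outside every neighbour's expanded sphere.  No random
numbers are involved, so results are bit-reproducible.

The buried interface area between groups A and B is
``S_buried = (S_A + S_B - S_AB) / 2`` with S_A and S_B computed on each
group in isolation and S_AB on the union.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .core import Frame, Selection, Topology, Trajectory, select

__all__ = ["SASAResult", "BuriedArea", "fibonacci_sphere", "sasa",
           "buried_area", "buried_area_series",
           "PROBE_RADIUS", "N_SPHERE_POINTS"]

PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 960


@dataclass
class SASAResult:
    atom_indices: np.ndarray
    atom_area: np.ndarray        # A^2 per selected atom
    residue_labels: list
    residue_area: np.ndarray     # A^2 per residue
    total: float                 # A^2
    probe: float
    n_points: int


@dataclass
class BuriedArea:
    s_a: float
    s_b: float
    s_ab: float
    s_buried: float
    series: Optional[np.ndarray] = None     # per sampled frame
    mean: Optional[float] = None
    sd: Optional[float] = None

    def __post_init__(self):
        expected = (self.s_a + self.s_b - self.s_ab) / 2.0
        if abs(self.s_buried - expected) > 1e-9:
            raise ValueError("S_buried != (S_A + S_B - S_AB)/2")


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice of ``n`` points."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    i = np.arange(n, dtype=float) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _sasa_atoms(coords: np.ndarray, radii: np.ndarray, probe: float,
                n_points: int) -> np.ndarray:
    """Per-atom accessible area for one coordinate set."""
    expanded = radii + probe
    unit = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    rmax = expanded.max()
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * unit
        neigh = tree.query_ball_point(coords[i], expanded[i] + rmax)
        neigh = [j for j in neigh if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 >= expanded[j] ** 2
        frac = accessible.mean()
        areas[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return areas


def sasa(frame: Frame, topology: Topology, sel: Optional[Selection] = None,
         probe: float = PROBE_RADIUS, n_points: int = N_SPHERE_POINTS,
         include_hydrogens: bool = False) -> SASAResult:
    """Shrake-Rupley SASA of the selected atoms (heavy atoms by default)."""
    sel = Selection() if sel is None else sel
    if not include_hydrogens:
        sel = sel & Selection(heavy_only=True)
    idx = select(topology, sel)
    if idx.size == 0:
        raise ValueError("empty selection for SASA")
    radii = topology.vdw_radii[idx]
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        bad = topology.elements[idx][~np.isfinite(radii) | (radii <= 0)]
        raise ValueError(f"missing van der Waals radius for element(s) "
                         f"{sorted(set(bad))}")
    areas = _sasa_atoms(frame.coords[idx], radii, probe, n_points)
    res_of = topology.atom_residue_index[idx]
    labels, res_area = [], []
    for r in sorted(set(res_of.tolist())):
        labels.append(topology.residue_label(r))
        res_area.append(areas[res_of == r].sum())
    return SASAResult(atom_indices=idx, atom_area=areas,
                      residue_labels=labels,
                      residue_area=np.array(res_area),
                      total=float(areas.sum()), probe=probe,
                      n_points=n_points)


def buried_area(frame: Frame, topology: Topology, sel_a: Selection,
                sel_b: Selection, probe: float = PROBE_RADIUS,
                n_points: int = N_SPHERE_POINTS) -> BuriedArea:
    """Buried interface area of two disjoint groups in one frame.

    S_A and S_B are computed with the other group's atoms absent, S_AB on
    the union; S_buried = (S_A + S_B - S_AB)/2.
    """
    heavy = Selection(heavy_only=True)
    ia = select(topology, sel_a & heavy)
    ib = select(topology, sel_b & heavy)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("empty group selection")
    if np.intersect1d(ia, ib).size:
        raise ValueError("groups overlap; buried area needs disjoint groups")
    radii = topology.vdw_radii

    def total(indices):
        return _sasa_atoms(frame.coords[indices], radii[indices], probe,
                           n_points).sum()

    s_a = float(total(ia))
    s_b = float(total(ib))
    s_ab = float(total(np.concatenate([ia, ib])))
    return BuriedArea(s_a=s_a, s_b=s_b, s_ab=s_ab,
                      s_buried=(s_a + s_b - s_ab) / 2.0)


def buried_area_series(traj: Trajectory, sel_a: Selection, sel_b: Selection,
                       probe: float = PROBE_RADIUS,
                       n_points: int = N_SPHERE_POINTS,
                       stride: int = 1) -> BuriedArea:
    """Per-frame buried area with mean and standard deviation."""
    sampled = np.arange(0, traj.n_frames, stride)
    vals = []
    last = None
    for f in sampled:
        last = buried_area(traj.frame(int(f)), traj.topology, sel_a, sel_b,
                           probe=probe, n_points=n_points)
        vals.append(last.s_buried)
    series = np.array(vals)
    return BuriedArea(s_a=last.s_a, s_b=last.s_b, s_ab=last.s_ab,
                      s_buried=last.s_buried, series=series,
                      mean=float(series.mean()),
                      sd=float(series.std(ddof=0)))
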