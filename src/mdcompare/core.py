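"""Core domain types for comparative MD trajectory analysis.

Conventions used throughout the package: lengths in Angstrom, times in
picoseconds, energies in kcal/mol, temperatures in Kelvin.  Residues are
identified by ``(chain, resid)`` with 1-based PDB residue numbers;
insertion codes are not supported.  Reports label residues in the
chain-prefixed style ``L:R113``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "Frame",
    "Trajectory",
    "Selection",
    "select",
    "infer_element",
    "vdw_radius_of",
    "mass_of",
    "WATER_RESNAMES",
    "THREE_TO_ONE",
]

#: Default residue names recognised as water.
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "HIE": "H", "HID": "H", "HIP": "H",
}


def _load_element_table() -> tuple[dict, dict]:
    text = resources.files("mdcompare.data").joinpath("elements.json").read_text()
    table = json.loads(text)
    return table["vdw_radius"], table["mass"]


_VDW_RADII, _MASSES = _load_element_table()

_TWO_LETTER_ELEMENTS = {
    "CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CU", "SE", "CA",
}


def infer_element(name: str, resname: str = "") -> str:
    """Infer an element symbol from a PDB atom name.

    Follows the usual PDB heuristics: names starting with a digit are
    hydrogens (``1HB``), calcium/metal two-letter symbols are only
    accepted for HETATM-style monatomic residues so that ``CA`` in a
    protein residue stays a carbon alpha.
    """
    name = name.strip().upper()
    if not name:
        raise ValueError("cannot infer element from empty atom name")
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    if resname.strip().upper() == name and name in _TWO_LETTER_ELEMENTS:
        return name  # monatomic ion residue, e.g. resname CA / atom CA
    first = name[0]
    if first == "H":
        return "H"
    if name[:2] in _TWO_LETTER_ELEMENTS and name[:2] not in ("CA",):
        return name[:2]
    return first


def vdw_radius_of(element: str, radii: Optional[dict] = None) -> float:
    table = radii if radii is not None else _VDW_RADII
    key = element.strip().upper()
    if key not in table:
        raise KeyError(f"no van der Waals radius for element {element!r}")
    return float(table[key])


def mass_of(element: str) -> float:
    key = element.strip().upper()
    if key not in _MASSES:
        raise KeyError(f"no atomic mass for element {element!r}")
    return float(_MASSES[key])


@dataclass(frozen=True)
class Atom:
    """A single atom record (one per topology position, frame-independent)."""

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    bfactor_exp: float  # experimental B-factor (A^2); NaN when absent
    vdw_radius: float

    def __post_init__(self):
        if not self.vdw_radius > 0:
            raise ValueError(f"vdw_radius must be positive, got {self.vdw_radius}")

    @property
    def label(self) -> str:
        one = THREE_TO_ONE.get(self.resname.upper(), self.resname)
        return f"{self.chain}:{one}{self.resid}"


class Topology:
    """Immutable atom table with a residue index.

    Atoms are stored as parallel numpy arrays for vectorised geometry;
    :meth:`atom` materialises individual :class:`Atom` records.  Residue
    spans partition the atom list: atoms of one residue are contiguous.
    """

    def __init__(self, atoms: Sequence[Atom],
                 water_resnames: Iterable[str] = WATER_RESNAMES):
        if len(atoms) == 0:
            raise ValueError("topology must contain at least one atom")
        self._serials = np.array([a.serial for a in atoms], dtype=np.int64)
        self._names = np.array([a.name for a in atoms], dtype=object)
        self._elements = np.array([a.element.upper() for a in atoms], dtype=object)
        self._resnames = np.array([a.resname for a in atoms], dtype=object)
        self._resids = np.array([a.resid for a in atoms], dtype=np.int64)
        self._chains = np.array([a.chain for a in atoms], dtype=object)
        self._bfactors = np.array([a.bfactor_exp for a in atoms], dtype=np.float64)
        self._radii = np.array([a.vdw_radius for a in atoms], dtype=np.float64)
        self._masses = np.array([mass_of(e) for e in self._elements],
                                dtype=np.float64)
        self.water_resnames = frozenset(r.upper() for r in water_resnames)

        keys = list(zip(self._chains, self._resids))
        seen: dict[tuple, int] = {}
        spans: list[list[int]] = []
        res_index = np.empty(len(atoms), dtype=np.int64)
        for i, key in enumerate(keys):
            if key in seen:
                ridx = seen[key]
                if spans[ridx][1] != i:
                    raise ValueError(
                        f"residue {key} is not contiguous in the atom list")
                spans[ridx][1] = i + 1
            else:
                seen[key] = len(spans)
                ridx = len(spans)
                spans.append([i, i + 1])
            res_index[i] = ridx
        dup = {}
        for i in range(len(atoms)):
            k = (self._chains[i], self._resids[i], self._names[i])
            if k in dup:
                raise ValueError(f"duplicate atom {k} in topology")
            dup[k] = i
        self._res_spans = tuple((s, e) for s, e in spans)
        self._atom_res = res_index
        self._res_keys = tuple(sorted(seen, key=seen.get))
        self._res_lookup = dict(seen)
        for arr in (self._serials, self._resids, self._bfactors, self._radii,
                    self._masses, self._atom_res):
            arr.setflags(write=False)

    # -- basic accessors -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self._serials)

    @property
    def n_residues(self) -> int:
        return len(self._res_spans)

    @property
    def names(self) -> np.ndarray:
        return self._names

    @property
    def elements(self) -> np.ndarray:
        return self._elements

    @property
    def resnames(self) -> np.ndarray:
        return self._resnames

    @property
    def resids(self) -> np.ndarray:
        return self._resids

    @property
    def chains(self) -> np.ndarray:
        return self._chains

    @property
    def bfactors_exp(self) -> np.ndarray:
        return self._bfactors

    @property
    def vdw_radii(self) -> np.ndarray:
        return self._radii

    @property
    def masses(self) -> np.ndarray:
        return self._masses

    @property
    def atom_residue_index(self) -> np.ndarray:
        """Per-atom index into :attr:`residue_keys`."""
        return self._atom_res

    @property
    def residue_keys(self) -> tuple:
        """Ordered ``(chain, resid)`` keys, one per residue."""
        return self._res_keys

    @property
    def residue_spans(self) -> tuple:
        return self._res_spans

    def residue_atoms(self, chain: str, resid: int) -> np.ndarray:
        start, end = self._res_spans[self._res_lookup[(chain, resid)]]
        return np.arange(start, end)

    def residue_name(self, res_index: int) -> str:
        start, _ = self._res_spans[res_index]
        return str(self._resnames[start])

    def residue_label(self, res_index: int) -> str:
        chain, resid = self._res_keys[res_index]
        one = THREE_TO_ONE.get(self.residue_name(res_index).upper(),
                               self.residue_name(res_index))
        return f"{chain}:{one}{resid}"

    @property
    def water_mask(self) -> np.ndarray:
        """Boolean per-atom mask of water atoms."""
        return np.array([str(r).upper() in self.water_resnames
                         for r in self._resnames])

    def atom(self, i: int) -> Atom:
        return Atom(
            serial=int(self._serials[i]),
            name=str(self._names[i]),
            element=str(self._elements[i]),
            resname=str(self._resnames[i]),
            resid=int(self._resids[i]),
            chain=str(self._chains[i]),
            bfactor_exp=float(self._bfactors[i]),
            vdw_radius=float(self._radii[i]),
        )

    @property
    def atoms(self) -> list[Atom]:
        return [self.atom(i) for i in range(self.n_atoms)]

    def atom_label(self, i: int) -> str:
        return f"{self.atom(i).label}-{self._names[i]}"

    def __len__(self) -> int:
        return self.n_atoms

    def __eq__(self, other) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return (self.n_atoms == other.n_atoms
                and all(np.array_equal(a, b) for a, b in (
                    (self._names, other._names),
                    (self._chains, other._chains),
                    (self._resids, other._resids),
                    (self._resnames, other._resnames))))


@dataclass(frozen=True)
class Frame:
    """One trajectory snapshot: per-atom coordinates (A) and a time (ps)."""

    coords: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (n_atoms, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)


class Trajectory:
    """A topology plus an ordered stack of coordinate frames.

    Coordinates are held as one ``(n_frames, n_atoms, 3)`` float64 array;
    :meth:`frame` returns lightweight :class:`Frame` views.
    """

    def __init__(self, topology: Topology, coords: np.ndarray,
                 times: Optional[np.ndarray] = None):
        coords = np.asarray(coords, dtype=np.float64)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError(f"coords must be (n_frames, n_atoms, 3), "
                             f"got {coords.shape}")
        if coords.shape[0] < 1:
            raise ValueError("trajectory must have at least one frame")
        if coords.shape[1] != topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {coords.shape[1]} != topology "
                f"atom count {topology.n_atoms}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if times is None:
            times = np.arange(coords.shape[0], dtype=np.float64)
        times = np.asarray(times, dtype=np.float64)
        if times.shape != (coords.shape[0],):
            raise ValueError("times must have one entry per frame")
        if coords.shape[0] > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.topology = topology
        self.coords = coords
        self.times = times

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(coords=self.coords[i], time=float(self.times[i]))

    @property
    def frames(self) -> list[Frame]:
        return [self.frame(i) for i in range(self.n_frames)]

    def __len__(self) -> int:
        return self.n_frames

    def slice_frames(self, start: int = 0, stop: Optional[int] = None,
                     step: int = 1) -> "Trajectory":
        sl = slice(start, stop, step)
        return Trajectory(self.topology, self.coords[sl].copy(),
                          self.times[sl].copy())


_BACKBONE_HEAVY = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class Selection:
    """Conjunction of optional atom filters.

    ``None`` means "no constraint".  ``water`` restricts to water atoms
    when ``True`` and to non-water atoms when ``False``.  Two selections
    combine with ``&`` into their conjunction, so
    ``select(a & b) == intersect(select(a), select(b))``.
    """

    chains: Optional[frozenset] = None
    resid_min: Optional[int] = None
    resid_max: Optional[int] = None
    names: Optional[frozenset] = None
    elements: Optional[frozenset] = None
    calpha_only: bool = False
    heavy_only: bool = False
    water: Optional[bool] = None

    @staticmethod
    def all() -> "Selection":
        return Selection()

    @staticmethod
    def chain(*chains: str, **kw) -> "Selection":
        return Selection(chains=frozenset(chains), **kw)

    @staticmethod
    def calpha(**kw) -> "Selection":
        return Selection(calpha_only=True, **kw)

    def __and__(self, other: "Selection") -> "Selection":
        def isect(a, b):
            if a is None:
                return b
            if b is None:
                return a
            return frozenset(a) & frozenset(b)

        def merge_flag(a, b, what):
            if a is None:
                return b
            if b is None:
                return a
            if a != b:
                raise ValueError(f"contradictory {what} filters")
            return a

        rmin = self.resid_min if other.resid_min is None else (
            other.resid_min if self.resid_min is None
            else max(self.resid_min, other.resid_min))
        rmax = self.resid_max if other.resid_max is None else (
            other.resid_max if self.resid_max is None
            else min(self.resid_max, other.resid_max))
        return Selection(
            chains=isect(self.chains, other.chains),
            resid_min=rmin, resid_max=rmax,
            names=isect(self.names, other.names),
            elements=isect(self.elements, other.elements),
            calpha_only=self.calpha_only or other.calpha_only,
            heavy_only=self.heavy_only or other.heavy_only,
            water=merge_flag(self.water, other.water, "water"),
        )

    def mask(self, topology: Topology) -> np.ndarray:
        m = np.ones(topology.n_atoms, dtype=bool)
        if self.chains is not None:
            m &= np.isin(topology.chains, list(self.chains))
        if self.resid_min is not None:
            m &= topology.resids >= self.resid_min
        if self.resid_max is not None:
            m &= topology.resids <= self.resid_max
        if self.names is not None:
            m &= np.isin(topology.names, list(self.names))
        if self.elements is not None:
            m &= np.isin(topology.elements, list(self.elements))
        if self.calpha_only:
            m &= (topology.names == "CA") & (topology.elements == "C")
        if self.heavy_only:
            m &= topology.elements != "H"
        if self.water is not None:
            wm = topology.water_mask
            m &= wm if self.water else ~wm
        return m

    @staticmethod
    def parse(text: str) -> "Selection":
        """Parse a small 'chain L and name CA' style selection grammar.

        Clauses joined by ``and``: ``chain A[,B]``, ``resid LO-HI`` (or a
        single number), ``name N1[,N2]``, ``element E1[,E2]``, ``calpha``,
        ``heavy``, ``water``, ``protein``/``nonwater``, ``all``.
        """
        sel = Selection()
        text = text.strip()
        if not text or text.lower() == "all":
            return sel
        for clause in [c.strip() for c in text.split(" and ")]:
            parts = clause.split(None, 1)
            kw = parts[0].lower()
            arg = parts[1].strip() if len(parts) > 1 else ""
            if kw == "chain":
                sel = sel & Selection(chains=frozenset(
                    a.strip() for a in arg.split(",")))
            elif kw == "resid":
                if "-" in arg.strip("- "):
                    lo, hi = arg.split("-", 1)
                    sel = sel & Selection(resid_min=int(lo), resid_max=int(hi))
                else:
                    sel = sel & Selection(resid_min=int(arg), resid_max=int(arg))
            elif kw == "name":
                sel = sel & Selection(names=frozenset(
                    a.strip().upper() for a in arg.split(",")))
            elif kw == "element":
                sel = sel & Selection(elements=frozenset(
                    a.strip().upper() for a in arg.split(",")))
            elif kw == "calpha":
                sel = sel & Selection(calpha_only=True)
            elif kw == "heavy":
                sel = sel & Selection(heavy_only=True)
            elif kw == "water":
                sel = sel & Selection(water=True)
            elif kw in ("protein", "nonwater"):
                sel = sel & Selection(water=False)
            else:
                raise ValueError(f"unknown selection clause {clause!r}")
        return sel


def select(obj: "Trajectory | Topology", sel: Selection) -> np.ndarray:
    """Resolve a selection to sorted atom indices (stable across frames)."""
    topology = obj.topology if isinstance(obj, Trajectory) else obj
    idx = np.flatnonzero(sel.mask(topology))
    if idx.size == 0:
        warnings.warn("selection matched no atoms", stacklevel=2)
    return idx
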