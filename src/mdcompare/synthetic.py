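"""Synthetic two-chain complex trajectories with planted, recoverable structure.

The generator emulates the statistical features a comparative trajectory
analysis consumes — per-residue positional fluctuation amplitudes,
inter-chain residue contacts that break at known frames, hydrogen bonds
with known per-frame persistence, salt bridges at set distances, bridging
waters, and bulk solvent — on top of an idealised extended-chain geometry.
It is deliberately not a physical model: there is no force field and no
realistic stereochemistry beyond PDB atom-naming conventions.  Downstream
statistics depend only on the stationary distribution of coordinates, so
an isotropic Gaussian displacement model per residue suffices.

Every residue hosting a planted feature is held fixed (its fluctuation
amplitude is forced to zero) so that the planted geometry is exact in
every frame; fluctuation-recovery tests therefore read amplitudes off
residues that host no feature.

Layout: chain A ("L") runs along x at y ~ 0, chain B ("N") parallel at
y ~ 10 A; side chains point away from the interface except where a plan
places them.  Waters sit far from both chains unless planted as bridges.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Atom, Frame, Topology, Trajectory

__all__ = [
    "ContactPlan", "HBondPlan", "SaltBridgePlan", "SyntheticSpec",
    "generate", "paper_contact_fixture",
]

CHAIN_A = "L"
CHAIN_B = "N"
_CA_SPACING = 3.8
_CHAIN_B_Y = 10.0
# planted-geometry constants (A)
_CONTACT_DIST = 4.0        # min heavy-atom distance of a live planted contact
_BROKEN_DIST = 8.0         # after the break frame
_OH = 0.96                 # O-H bond length
_HA_ON = 2.2               # H...acceptor distance of a live planted H-bond
_OFF_SHIFT = 5.0           # displacement applied to break a planted bond
_WATER_GAP = 5.6           # partner-partner distance across a bridge water
_BRIDGE_Z = 4.0            # bridge assemblies sit out of the backbone plane


@dataclass(frozen=True)
class ContactPlan:
    """An inter-chain residue contact; broken from ``break_frame`` on."""
    res_a: int
    res_b: int
    break_frame: Optional[int] = None


@dataclass(frozen=True)
class HBondPlan:
    """A donor(chain A)-H...acceptor(chain B) bond, live with probability
    ``persistence`` independently per frame."""
    res_a: int
    res_b: int
    persistence: float = 1.0


@dataclass(frozen=True)
class SaltBridgePlan:
    """An acidic/basic side-chain pair at ``distance`` A (N-O).

    ``bidentate=True`` plants ASP(OD1,OD2)/ARG(NH1,NH2) with two qualifying
    O-N pairs; ``False`` plants GLU(OE1)/LYS(NZ) with a single pair.
    """
    res_a: int
    res_b: int
    distance: float = 3.5
    bidentate: bool = True


@dataclass
class SyntheticSpec:
    """Full description of a synthetic two-chain system."""

    n_res_a: int = 20
    n_res_b: int = 20
    n_frames: int = 100
    dt: float = 1.0
    rmsf_profile: Optional[np.ndarray] = None   # len n_res_a + n_res_b, A
    contact_plan: Sequence[ContactPlan] = field(default_factory=tuple)
    hbond_plan: Sequence[HBondPlan] = field(default_factory=tuple)
    saltbridge_plan: Sequence[SaltBridgePlan] = field(default_factory=tuple)
    n_bridge_waters: int = 0
    bridge_persistence: float = 0.95
    n_bulk_waters: int = 0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_res_a", "n_res_b", "n_frames", "n_bridge_waters",
                     "n_bulk_waters"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_res_a < 1 or self.n_res_b < 1 or self.n_frames < 1:
            raise ValueError("need at least one residue per chain and one frame")
        if not 0.0 <= self.bridge_persistence <= 1.0:
            raise ValueError("bridge_persistence must be in [0, 1]")
        for hb in self.hbond_plan:
            if not 0.0 <= hb.persistence <= 1.0:
                raise ValueError("persistence must be in [0, 1]")
        n_res = self.n_res_a + self.n_res_b
        if self.rmsf_profile is None:
            self.rmsf_profile = np.zeros(n_res)
        self.rmsf_profile = np.asarray(self.rmsf_profile, dtype=float)
        if self.rmsf_profile.shape != (n_res,):
            raise ValueError(f"rmsf_profile must have length {n_res}")
        if np.any(self.rmsf_profile < 0):
            raise ValueError("fluctuation amplitudes must be >= 0")
        for cp in self.contact_plan:
            if cp.break_frame is not None and not (
                    0 <= cp.break_frame <= self.n_frames):
                raise ValueError("break_frame outside trajectory")
        for plan in (tuple(self.contact_plan) + tuple(self.hbond_plan)
                     + tuple(self.saltbridge_plan)):
            if not (1 <= plan.res_a <= self.n_res_a
                    and 1 <= plan.res_b <= self.n_res_b):
                raise ValueError(f"plan references residue outside chains: {plan}")

    def to_json(self) -> str:
        d = {
            "n_res_a": self.n_res_a, "n_res_b": self.n_res_b,
            "n_frames": self.n_frames, "dt": self.dt,
            "rmsf_profile": list(map(float, self.rmsf_profile)),
            "contact_plan": [[c.res_a, c.res_b, c.break_frame]
                             for c in self.contact_plan],
            "hbond_plan": [[h.res_a, h.res_b, h.persistence]
                           for h in self.hbond_plan],
            "saltbridge_plan": [[s.res_a, s.res_b, s.distance, s.bidentate]
                                for s in self.saltbridge_plan],
            "n_bridge_waters": self.n_bridge_waters,
            "bridge_persistence": self.bridge_persistence,
            "n_bulk_waters": self.n_bulk_waters, "seed": self.seed,
        }
        return json.dumps(d, indent=1)

    @staticmethod
    def from_json(text: str) -> "SyntheticSpec":
        d = json.loads(text)
        return SyntheticSpec(
            n_res_a=d["n_res_a"], n_res_b=d["n_res_b"],
            n_frames=d["n_frames"], dt=d.get("dt", 1.0),
            rmsf_profile=np.array(d["rmsf_profile"], dtype=float)
            if d.get("rmsf_profile") is not None else None,
            contact_plan=tuple(ContactPlan(*c) for c in d.get("contact_plan", [])),
            hbond_plan=tuple(HBondPlan(*h) for h in d.get("hbond_plan", [])),
            saltbridge_plan=tuple(SaltBridgePlan(*s)
                                  for s in d.get("saltbridge_plan", [])),
            n_bridge_waters=d.get("n_bridge_waters", 0),
            bridge_persistence=d.get("bridge_persistence", 0.95),
            n_bulk_waters=d.get("n_bulk_waters", 0),
            seed=d.get("seed", 0),
        )


def _backbone(resid: int, chain: str) -> dict:
    """Idealised extended-chain backbone positions for one residue."""
    x = _CA_SPACING * (resid - 1)
    if chain == CHAIN_A:
        y0, sign = 0.0, 1.0
    else:
        y0, sign = _CHAIN_B_Y, -1.0
    # zig-zag in y/z keeps phi/psi well defined and, crucially, makes the
    # C-alpha trace non-collinear so rigid superposition is well posed
    dz = 0.6 if resid % 2 else -0.6
    return {
        "N":  np.array([x - 1.2, y0 + 0.4 * sign, dz + 0.2]),
        "CA": np.array([x, y0, dz]),
        "C":  np.array([x + 1.2, y0 + 0.4 * sign, dz - 0.2]),
        "O":  np.array([x + 1.2, y0 + 1.6 * sign, dz - 0.4]),
    }


def _default_sidechain(resid: int, chain: str) -> np.ndarray:
    x = _CA_SPACING * (resid - 1)
    if chain == CHAIN_A:
        return np.array([x, -1.5, 0.0])     # points away from interface
    return np.array([x, _CHAIN_B_Y + 1.5, 0.0])


class _Builder:
    """Accumulates atoms and per-atom base positions, detecting conflicts."""

    def __init__(self):
        self.atoms: list[Atom] = []
        self.base: list[np.ndarray] = []
        self._where: dict[tuple, int] = {}

    def add(self, chain, resid, resname, name, element, pos, radius):
        key = (chain, resid, name)
        pos = np.asarray(pos, dtype=float)
        if key in self._where:
            i = self._where[key]
            if np.linalg.norm(self.base[i] - pos) > 0.5:
                raise ValueError(
                    f"geometrically unsatisfiable plan: atom {key} placed at "
                    f"two positions more than 0.5 A apart")
            return i
        self._where[key] = len(self.atoms)
        self.atoms.append(Atom(serial=len(self.atoms) + 1, name=name,
                               element=element, resname=resname, resid=resid,
                               chain=chain, bfactor_exp=float("nan"),
                               vdw_radius=radius))
        self.base.append(pos)
        return len(self.atoms) - 1

    def has(self, chain, resid, name):
        return (chain, resid, name) in self._where

    def index(self, chain, resid, name):
        return self._where[(chain, resid, name)]


_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "H": 1.20}


def generate(spec: SyntheticSpec, with_truth: bool = False):
    """Build the trajectory described by ``spec``.

    Deterministic given ``spec.seed``.  With ``with_truth=True`` also
    returns a dict of realised ground truth (planted contact pairs and
    break frames, per-frame H-bond presence, water-bridge presence) for
    test harnesses.
    """
    rng = np.random.default_rng(spec.seed)
    b = _Builder()

    # role bookkeeping: which residues host which feature
    role: dict[tuple, str] = {}

    def claim(chain, resid, what):
        key = (chain, resid)
        if key in role and role[key] != what:
            raise ValueError(
                f"geometrically unsatisfiable plan: residue {key} hosts both "
                f"{role[key]} and {what}")
        role[key] = what

    for cp in spec.contact_plan:
        claim(CHAIN_A, cp.res_a, "contact")
        claim(CHAIN_B, cp.res_b, "contact")
    for hb in spec.hbond_plan:
        claim(CHAIN_A, hb.res_a, "hbond")
        claim(CHAIN_B, hb.res_b, "hbond")
    for sb in spec.saltbridge_plan:
        claim(CHAIN_A, sb.res_a, "saltbridge")
        claim(CHAIN_B, sb.res_b, "saltbridge")
    bridge_partner_a = []
    bridge_partner_b = []
    if spec.n_bridge_waters:
        # bridge partners occupy the highest-numbered feature-free residues
        free_a = [r for r in range(spec.n_res_a, 0, -1)
                  if (CHAIN_A, r) not in role]
        free_b = [r for r in range(spec.n_res_b, 0, -1)
                  if (CHAIN_B, r) not in role]
        if (len(free_a) < spec.n_bridge_waters
                or len(free_b) < spec.n_bridge_waters):
            raise ValueError("not enough feature-free residues to host "
                             "bridge-water partners")
        for k in range(spec.n_bridge_waters):
            ra, rb = free_a[k], free_b[k]
            claim(CHAIN_A, ra, "waterbridge")
            claim(CHAIN_B, rb, "waterbridge")
            bridge_partner_a.append(ra)
            bridge_partner_b.append(rb)

    def resname_for(chain, resid):
        what = role.get((chain, resid))
        if what == "hbond":
            return "SER" if chain == CHAIN_A else "GLN"
        if what == "saltbridge":
            plans = [sb for sb in spec.saltbridge_plan
                     if (chain == CHAIN_A and sb.res_a == resid)
                     or (chain == CHAIN_B and sb.res_b == resid)]
            sb = plans[0]
            if chain == CHAIN_A:
                return "ASP" if sb.bidentate else "GLU"
            return "ARG" if sb.bidentate else "LYS"
        if what == "waterbridge":
            return "SER"
        return "ALA"

    # --- protein atoms, chain A then chain B, residues in order ----------
    for chain, n_res in ((CHAIN_A, spec.n_res_a), (CHAIN_B, spec.n_res_b)):
        for resid in range(1, n_res + 1):
            resname = resname_for(chain, resid)
            bb = _backbone(resid, chain)
            for name in ("N", "CA", "C", "O"):
                b.add(chain, resid, resname, name, name[0], bb[name],
                      _RADII[name[0]])
            what = role.get((chain, resid))
            sc = _default_sidechain(resid, chain)
            x = _CA_SPACING * (resid - 1)
            if what is None:
                b.add(chain, resid, resname, "CB", "C", sc, _RADII["C"])
            elif what == "contact":
                b.add(chain, resid, resname, "CB", "C", sc, _RADII["C"])
            elif what == "hbond":
                if chain == CHAIN_A:   # SER donor: OG-HG
                    b.add(chain, resid, resname, "OG", "O",
                          [x, 3.0, 0.0], _RADII["O"])
                    b.add(chain, resid, resname, "HG", "H",
                          [x, 3.0 + _OH, 0.0], _RADII["H"])
                else:                  # GLN acceptor: OE1
                    b.add(chain, resid, resname, "OE1", "O",
                          [x, 3.0 + _OH + _HA_ON, 0.0], _RADII["O"])
            elif what == "saltbridge":
                plans = [sb for sb in spec.saltbridge_plan
                         if (chain == CHAIN_A and sb.res_a == resid)
                         or (chain == CHAIN_B and sb.res_b == resid)]
                sb = plans[0]
                d = sb.distance
                if sb.bidentate:
                    if chain == CHAIN_A:
                        b.add(chain, resid, "ASP", "CG", "C",
                              [x, 2.3, 0.0], _RADII["C"])
                        b.add(chain, resid, "ASP", "OD1", "O",
                              [x, 3.0, -0.6], _RADII["O"])
                        b.add(chain, resid, "ASP", "OD2", "O",
                              [x, 3.0, 0.6], _RADII["O"])
                    else:
                        xa = _CA_SPACING * (sb.res_a - 1)
                        b.add(chain, resid, "ARG", "NH1", "N",
                              [xa, 3.0 + d, -0.6], _RADII["N"])
                        b.add(chain, resid, "ARG", "NH2", "N",
                              [xa, 3.0 + d, 0.6], _RADII["N"])
                else:
                    if chain == CHAIN_A:
                        b.add(chain, resid, "GLU", "OE1", "O",
                              [x, 3.0, 0.0], _RADII["O"])
                    else:
                        xa = _CA_SPACING * (sb.res_a - 1)
                        b.add(chain, resid, "LYS", "NZ", "N",
                              [xa, 3.0 + d, 0.0], _RADII["N"])
            elif what == "waterbridge":
                k = (bridge_partner_a.index(resid) if chain == CHAIN_A
                     else bridge_partner_b.index(resid))
                xa = _CA_SPACING * (bridge_partner_a[k] - 1)
                if chain == CHAIN_A:
                    b.add(chain, resid, "SER", "OG", "O",
                          [xa, 3.0, _BRIDGE_Z], _RADII["O"])
                else:
                    b.add(chain, resid, "SER", "OG", "O",
                          [xa, 3.0 + _WATER_GAP, _BRIDGE_Z], _RADII["O"])

    # planted contact side chains (override default): live geometry
    contact_atom_pairs = []
    for cp in spec.contact_plan:
        xa = _CA_SPACING * (cp.res_a - 1)
        ia = b.index(CHAIN_A, cp.res_a, "CB")
        b.base[ia] = np.array([xa, 3.0, 0.0])
        ib = b.index(CHAIN_B, cp.res_b, "CB")
        b.base[ib] = np.array([xa, 3.0 + _CONTACT_DIST, 0.0])
        contact_atom_pairs.append((ia, ib))

    # --- waters ----------------------------------------------------------
    bridge_water_atoms = []
    for k in range(spec.n_bridge_waters):
        xa = _CA_SPACING * (bridge_partner_a[k] - 1)
        ow = np.array([xa, 3.0 + _WATER_GAP / 2.0, _BRIDGE_Z])
        h1 = ow + np.array([0.0, -_OH, 0.0])
        h2 = ow + np.array([0.0, _OH, 0.0])
        resid = 1000 + k
        io = b.add("W", resid, "WAT", "O", "O", ow, _RADII["O"])
        i1 = b.add("W", resid, "WAT", "H1", "H", h1, _RADII["H"])
        i2 = b.add("W", resid, "WAT", "H2", "H", h2, _RADII["H"])
        bridge_water_atoms.append((io, i1, i2))

    bulk_water_atoms = []
    n_side = max(1, int(np.ceil(spec.n_bulk_waters ** (1.0 / 3.0))))
    for k in range(spec.n_bulk_waters):
        gx, gy, gz = (k % n_side, (k // n_side) % n_side,
                      k // (n_side * n_side))
        ow = np.array([4.0 * gx, -20.0 - 4.0 * gy, 4.0 * gz])
        resid = 2000 + k
        io = b.add("W", resid, "WAT", "O", "O", ow, _RADII["O"])
        i1 = b.add("W", resid, "WAT", "H1", "H", ow + [_OH, 0, 0], _RADII["H"])
        i2 = b.add("W", resid, "WAT", "H2", "H",
                   ow + [-0.24, 0.93, 0.0], _RADII["H"])
        bulk_water_atoms.append((io, i1, i2))

    topology = Topology(b.atoms)
    base = np.array(b.base)
    n_atoms = base.shape[0]
    F = spec.n_frames

    # --- stochastic structure (fixed draw order for reproducibility) -----
    hbond_on = np.ones((len(spec.hbond_plan), F), dtype=bool)
    for j, hb in enumerate(spec.hbond_plan):
        hbond_on[j] = rng.random(F) < hb.persistence
    bridge_on = np.ones((spec.n_bridge_waters, F), dtype=bool)
    for k in range(spec.n_bridge_waters):
        bridge_on[k] = rng.random(F) < spec.bridge_persistence

    # per-residue isotropic Gaussian displacements; feature residues pinned
    n_res = spec.n_res_a + spec.n_res_b
    sigma = spec.rmsf_profile / np.sqrt(3.0)
    sigma = sigma.copy()
    res_keys = list(topology.residue_keys)
    for i, key in enumerate(res_keys[:n_res]):
        if key in role:
            sigma[i] = 0.0
    disp = rng.standard_normal((F, n_res, 3)) * sigma[None, :, None]

    coords = np.repeat(base[None, :, :], F, axis=0)
    # apply rigid per-residue protein displacements
    atom_res = topology.atom_residue_index
    protein_mask = atom_res < n_res
    coords[:, protein_mask, :] += disp[:, atom_res[protein_mask], :]

    # contact breaks: move the chain-B side chain away from the break frame on
    for (ia, ib), cp in zip(contact_atom_pairs, spec.contact_plan):
        if cp.break_frame is not None:
            coords[cp.break_frame:, ib, 1] += _BROKEN_DIST - _CONTACT_DIST

    # H-bond off frames: displace the acceptor out of range
    for j, hb in enumerate(spec.hbond_plan):
        off = ~hbond_on[j]
        iacc = b.index(CHAIN_B, hb.res_b, "OE1")
        coords[off, iacc, 1] += _OFF_SHIFT

    # water-bridge off frames: displace the whole water
    for k, (io, i1, i2) in enumerate(bridge_water_atoms):
        off = ~bridge_on[k]
        for i in (io, i1, i2):
            coords[off, i, 2] += _OFF_SHIFT

    times = np.arange(F, dtype=float) * spec.dt
    traj = Trajectory(topology, coords, times)
    if not with_truth:
        return traj

    truth = {
        "contacts": [{"pair": [[CHAIN_A, cp.res_a], [CHAIN_B, cp.res_b]],
                      "break_frame": cp.break_frame}
                     for cp in spec.contact_plan],
        "hbonds": [{
            "donor": f"{CHAIN_A}:{hb.res_a}:OG",
            "hydrogen": f"{CHAIN_A}:{hb.res_a}:HG",
            "acceptor": f"{CHAIN_B}:{hb.res_b}:OE1",
            "persistence": hb.persistence,
            "presence": hbond_on[j].tolist(),
            "occupancy": float(hbond_on[j].mean()),
        } for j, hb in enumerate(spec.hbond_plan)],
        "salt_bridges": [{
            "pair": [[CHAIN_A, sb.res_a], [CHAIN_B, sb.res_b]],
            "distance": sb.distance,
            "class": "bidentate" if sb.bidentate else "single",
        } for sb in spec.saltbridge_plan],
        "water_bridges": [{
            "water_resid": 1000 + k,
            "partner_a": f"{CHAIN_A}:{bridge_partner_a[k]}:OG",
            "partner_b": f"{CHAIN_B}:{bridge_partner_b[k]}:OG",
            "presence": bridge_on[k].tolist(),
            "occupancy": float(bridge_on[k].mean()),
        } for k in range(spec.n_bridge_waters)],
        "rmsf_profile": [float(s) * np.sqrt(3.0) for s in sigma],
        "pinned_residues": sorted([list(k) for k in role]),
    }
    return traj, truth


def paper_contact_fixture():
    """Abstract first/last-snapshot contact sets with the published counts.

    Returns ``{system: (initial_pairs, final_pairs)}`` for the two studied
    complexes, constructed so that (|initial|, |final|, |common|) equal
    (452, 427, 359) for PD-1/PD-L1 and (516, 505, 432) for Nano/PD-L1.
    The pairs are synthetic labels — the statistics depend only on counts.
    """
    def build(n_initial, n_final, n_common):
        common = {(("L", k), ("P", k)) for k in range(1, n_common + 1)}
        spec_i = {(("L", 10000 + k), ("P", 10000 + k))
                  for k in range(1, n_initial - n_common + 1)}
        spec_f = {(("L", 20000 + k), ("P", 20000 + k))
                  for k in range(1, n_final - n_common + 1)}
        return frozenset(common | spec_i), frozenset(common | spec_f)

    return {
        "PD-1/PD-L1": build(452, 427, 359),
        "Nano/PD-L1": build(516, 505, 432),
    }
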