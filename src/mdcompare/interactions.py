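"""Geometric interaction detectors and occupancy accounting.

Criteria (all purely geometric, evaluated per frame):

* hydrogen bond — acceptor...hydrogen distance < 3.5 A AND the
  acceptor-hydrogen-donor angle > 135 degrees.  Note the distance is
  measured to the *hydrogen*, not between the heavy atoms; a config
  switch (``distance_mode='donor-acceptor'``) selects the conventional
  donor-acceptor 3.5 A reading instead.
* salt bridge — side-chain O of Asp/Glu within 4 A of side-chain N of
  Arg/Lys/His.  A residue pair is classified *bidentate* when two or more
  distinct O-N pairs qualify simultaneously in at least half of the
  frames, *single* when one does, and *half* when the criterion holds in
  fewer than half of the frames (a temporal reading of "half
  salt-bridge", documented as this package's interpretation).
* water bridge — a water simultaneously hydrogen-bonded (same criterion)
  to one partner atom on each side, as donor or acceptor on either side.
* interface water census — waters with any atom within a cutoff
  (default 4 A) of any atom of a region of interest.

Donor/acceptor chemistry is driven by atom-name tables, not by bond
perception, so detection is deterministic and format-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .core import Selection, Topology, Trajectory, select
from .geometry import angle_at

__all__ = [
    "HBond", "SaltBridge", "WaterBridge",
    "donor_hydrogen_pairs", "acceptor_atoms",
    "detect_hbonds", "detect_salt_bridges", "detect_water_bridges",
    "interface_water_count",
    "brute_force_hbonds", "brute_force_salt_bridge_pairs",
]

HBOND_DIST = 3.5      # A, acceptor...hydrogen
HBOND_ANGLE = 135.0   # degrees, acceptor-hydrogen-donor
SALT_BRIDGE_DIST = 4.0
OCCUPANCY_REPORT = 0.40   # conventional reporting filter

#: side-chain atoms that qualify for salt bridges (name tables, editable)
ACIDIC_O = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_N = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",),
           "HIS": ("ND1", "NE2"), "HIE": ("ND1", "NE2"),
           "HID": ("ND1", "NE2"), "HIP": ("ND1", "NE2")}

#: sp2 nitrogen acceptors by (resname, atom name)
_N_ACCEPTORS = {("HIS", "ND1"), ("HIS", "NE2"), ("HIE", "ND1"),
                ("HID", "NE2"), ("ASN", "ND2x")}  # last entry inert guard


@dataclass
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    labels: tuple            # human-readable (donor, hydrogen, acceptor)
    presence: np.ndarray     # bool per sampled frame
    occupancy: float

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy outside [0, 1]")


@dataclass
class SaltBridge:
    residue_pair: tuple          # ((chain, resid), (chain, resid)) acid, base
    labels: tuple
    atom_pairs: list             # [(o_index, n_index), ...] qualifying pairs
    min_distance: np.ndarray     # per sampled frame, A
    n_qualifying: np.ndarray     # per sampled frame
    occupancy: float
    bridge_class: str            # half | single | bidentate


@dataclass
class WaterBridge:
    water: tuple                 # (chain, resid) of the water
    partner_a: int
    partner_b: int
    labels: tuple
    presence: np.ndarray
    occupancy: float


def donor_hydrogen_pairs(topology: Topology, donors: Selection
                         ) -> list[tuple[int, int]]:
    """(donor heavy atom, hydrogen) pairs from name rules within residues.

    A hydrogen ``Hxyz`` belongs to the N/O heavy atom of the same residue
    whose name tail matches ``xyz`` (optionally with a trailing index
    digit dropped, covering names like HH11 -> NH1); water hydrogens
    belong to the water oxygen; a bare backbone ``H``/``HN`` belongs
    to ``N``.
    """
    didx = set(select(topology, donors).tolist())
    water = topology.water_mask
    pairs = []
    for start, end in topology.residue_spans:
        atoms = range(start, end)
        heavies = {str(topology.names[i]): i for i in atoms
                   if topology.elements[i] in ("N", "O")}
        for i in atoms:
            if topology.elements[i] != "H":
                continue
            name = str(topology.names[i]).upper()
            donor = None
            if water[i]:
                donor = heavies["O"] if "O" in heavies else heavies.get("OW")
            elif name in ("H", "HN", "H1", "H2", "H3"):
                donor = heavies.get("N")
            else:
                tail = name.lstrip("0123456789")[1:]
                for cand, j in heavies.items():
                    if cand[1:] == tail or (len(tail) > 1
                                            and cand[1:] == tail[:-1]):
                        donor = j
                        break
            if donor is not None and donor in didx:
                pairs.append((donor, i))
    return pairs


def acceptor_atoms(topology: Topology, acceptors: Selection) -> np.ndarray:
    """Acceptor candidates: any oxygen, plus histidine ring nitrogens."""
    idx = select(topology, acceptors)
    keep = []
    for i in idx:
        if topology.elements[i] == "O":
            keep.append(i)
        elif (str(topology.resnames[i]).upper(),
              str(topology.names[i])) in _N_ACCEPTORS:
            keep.append(i)
    return np.array(keep, dtype=int)


def _hbond_presence(coords, d_atoms, h_atoms, a_atoms, dist_cutoff,
                    angle_cutoff, distance_mode):
    """Vectorised per-frame presence for all (D,H) x A combinations."""
    H = coords[h_atoms]          # (nDH, 3)
    D = coords[d_atoms]
    A = coords[a_atoms]          # (nA, 3)
    ref = H if distance_mode == "acceptor-hydrogen" else D
    diff = ref[:, None, :] - A[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    ok = dist < dist_cutoff
    if not ok.any():
        return ok
    ii, jj = np.nonzero(ok)
    ang = angle_at(A[jj], H[ii], D[ii])
    ok[ii, jj] = ang > angle_cutoff
    return ok


def detect_hbonds(traj: Trajectory, donors: Selection, acceptors: Selection,
                  dist_cutoff: float = HBOND_DIST,
                  angle_cutoff: float = HBOND_ANGLE, stride: int = 1,
                  distance_mode: str = "acceptor-hydrogen",
                  min_occupancy: float = 0.0) -> list[HBond]:
    """Hydrogen bonds between donor-side and acceptor-side selections.

    Presence per sampled frame, occupancy over the sampled frames; set
    ``min_occupancy=0.40`` for the conventional reporting filter.
    """
    top = traj.topology
    dh = donor_hydrogen_pairs(top, donors)
    if not dh:
        raise ValueError(
            "no donor hydrogens found: hydrogen-bond detection requires "
            "MD-style topologies with explicit hydrogens")
    acc = acceptor_atoms(top, acceptors)
    if acc.size == 0:
        raise ValueError("no acceptor atoms in selection")
    d_atoms = np.array([d for d, _ in dh])
    h_atoms = np.array([h for _, h in dh])
    res_of = top.atom_residue_index
    sampled = np.arange(0, traj.n_frames, stride)
    pres = np.zeros((len(dh), acc.size, sampled.size), dtype=bool)
    for col, f in enumerate(sampled):
        pres[:, :, col] = _hbond_presence(
            traj.coords[f], d_atoms, h_atoms, acc, dist_cutoff, angle_cutoff,
            distance_mode)
    out = []
    for i in range(len(dh)):
        for j in range(acc.size):
            if res_of[d_atoms[i]] == res_of[acc[j]]:
                continue  # intra-residue pseudo-bonds are not reported
            row = pres[i, j]
            if not row.any():
                continue
            occ = float(row.mean())
            if occ < min_occupancy:
                continue
            out.append(HBond(
                donor=int(d_atoms[i]), hydrogen=int(h_atoms[i]),
                acceptor=int(acc[j]),
                labels=(top.atom_label(int(d_atoms[i])),
                        top.atom_label(int(h_atoms[i])),
                        top.atom_label(int(acc[j]))),
                presence=row.copy(), occupancy=occ))
    out.sort(key=lambda hb: -hb.occupancy)
    return out


def brute_force_hbonds(traj: Trajectory, donors: Selection,
                       acceptors: Selection,
                       dist_cutoff: float = HBOND_DIST,
                       angle_cutoff: float = HBOND_ANGLE,
                       frame: int = 0) -> set:
    """Oracle: plain triple loop over (D,H) x A for one frame."""
    top = traj.topology
    coords = traj.coords[frame]
    res_of = top.atom_residue_index
    found = set()
    for d, h in donor_hydrogen_pairs(top, donors):
        for a in acceptor_atoms(top, acceptors):
            if res_of[d] == res_of[a]:
                continue
            dist = float(np.linalg.norm(coords[a] - coords[h]))
            ang = float(angle_at(coords[a], coords[h], coords[d]))
            if dist < dist_cutoff and ang > angle_cutoff:
                found.add((d, h, int(a)))
    return found


def _salt_bridge_atoms(topology: Topology, sel: Selection):
    idx = select(topology, sel)
    o_atoms, n_atoms = [], []
    for i in idx:
        resname = str(topology.resnames[i]).upper()
        name = str(topology.names[i])
        if resname in ACIDIC_O and name in ACIDIC_O[resname]:
            o_atoms.append(i)
        if resname in BASIC_N and name in BASIC_N[resname]:
            n_atoms.append(i)
    return np.array(o_atoms, dtype=int), np.array(n_atoms, dtype=int)


def detect_salt_bridges(traj: Trajectory, group_a: Selection,
                        group_b: Selection,
                        cutoff: float = SALT_BRIDGE_DIST,
                        stride: int = 1) -> list[SaltBridge]:
    """Salt bridges between two groups (acid on either side)."""
    top = traj.topology
    oa, na = _salt_bridge_atoms(top, group_a)
    ob, nb = _salt_bridge_atoms(top, group_b)
    candidates = [(o, n) for o in oa for n in nb] + \
                 [(o, n) for o in ob for n in na]
    if not candidates:
        return []
    res_of = top.atom_residue_index
    keys = top.residue_keys
    sampled = np.arange(0, traj.n_frames, stride)
    o_idx = np.array([o for o, _ in candidates])
    n_idx = np.array([n for _, n in candidates])
    dist = np.sqrt(((traj.coords[sampled][:, o_idx, :]
                     - traj.coords[sampled][:, n_idx, :]) ** 2).sum(axis=2)).T
    # group candidate atom pairs by residue pair
    groups: dict[tuple, list[int]] = {}
    for k, (o, n) in enumerate(candidates):
        pair = (keys[res_of[o]], keys[res_of[n]])
        groups.setdefault(pair, []).append(k)
    out = []
    for pair, ks in sorted(groups.items()):
        d = dist[ks]                       # (n_atom_pairs, n_samples)
        within = d < cutoff
        n_qual = within.sum(axis=0)
        if not (n_qual > 0).any():
            continue
        occ = float((n_qual > 0).mean())
        if occ < 0.5:
            cls = "half"
        elif float((n_qual >= 2).mean()) >= 0.5:
            cls = "bidentate"
        else:
            cls = "single"
        ra = top.residue_label(res_of[candidates[ks[0]][0]])
        rb = top.residue_label(res_of[candidates[ks[0]][1]])
        out.append(SaltBridge(
            residue_pair=pair,
            labels=(ra, rb),
            atom_pairs=[tuple(map(int, candidates[k])) for k in ks],
            min_distance=d.min(axis=0),
            n_qualifying=n_qual,
            occupancy=occ,
            bridge_class=cls))
    return out


def brute_force_salt_bridge_pairs(traj: Trajectory, group_a: Selection,
                                  group_b: Selection,
                                  cutoff: float = SALT_BRIDGE_DIST,
                                  frame: int = 0) -> set:
    """Oracle: all qualifying O-N atom pairs in one frame, double loop."""
    top = traj.topology
    coords = traj.coords[frame]
    oa, na = _salt_bridge_atoms(top, group_a)
    ob, nb = _salt_bridge_atoms(top, group_b)
    found = set()
    for olist, nlist in ((oa, nb), (ob, na)):
        for o in olist:
            for n in nlist:
                if np.linalg.norm(coords[o] - coords[n]) < cutoff:
                    found.add((int(o), int(n)))
    return found


def detect_water_bridges(traj: Trajectory, partners_a: Selection,
                         partners_b: Selection, stride: int = 1,
                         dist_cutoff: float = HBOND_DIST,
                         angle_cutoff: float = HBOND_ANGLE
                         ) -> tuple[list[WaterBridge], dict]:
    """Water-mediated hydrogen bonds between two partner selections.

    Returns the per-water bridge records and a "dynamic relay" summary:
    per partner-pair occupancy with ANY water, capturing relays where the
    mediating water changes identity over time.
    """
    top = traj.topology
    if not top.water_mask.any():
        raise ValueError("no waters in topology")
    water_sel = Selection(water=True)
    pa = _polar_partner_atoms(top, partners_a)
    pb = _polar_partner_atoms(top, partners_b)
    if pa.size == 0 or pb.size == 0:
        raise ValueError("no polar partner atoms in selection")
    sampled = np.arange(0, traj.n_frames, stride)
    # per-frame H-bond presence between each water and each partner atom,
    # with the water acting as donor or acceptor
    water_res = sorted({tuple(top.residue_keys[r]) for r in
                        set(top.atom_residue_index[select(top, water_sel)]
                            .tolist())})
    hb_wa = _water_partner_presence(traj, sampled, water_res, pa,
                                    dist_cutoff, angle_cutoff)
    hb_wb = _water_partner_presence(traj, sampled, water_res, pb,
                                    dist_cutoff, angle_cutoff)
    bridges = []
    any_water: dict[tuple, np.ndarray] = {}
    for wi, wkey in enumerate(water_res):
        for ai, a in enumerate(pa):
            if not hb_wa[wi, ai].any():
                continue
            for bi, b in enumerate(pb):
                both = hb_wa[wi, ai] & hb_wb[wi, bi]
                if not both.any():
                    continue
                bridges.append(WaterBridge(
                    water=wkey, partner_a=int(a), partner_b=int(b),
                    labels=(f"{wkey[0]}:{wkey[1]}", top.atom_label(int(a)),
                            top.atom_label(int(b))),
                    presence=both, occupancy=float(both.mean())))
                key = (int(a), int(b))
                any_water[key] = any_water.get(
                    key, np.zeros(sampled.size, dtype=bool)) | both
    relay = {
        (top.atom_label(a), top.atom_label(b)): float(v.mean())
        for (a, b), v in sorted(any_water.items())
    }
    bridges.sort(key=lambda w: -w.occupancy)
    return bridges, relay


def _polar_partner_atoms(topology: Topology, sel: Selection) -> np.ndarray:
    idx = select(topology, sel & Selection(water=False))
    return np.array([i for i in idx if topology.elements[i] in ("N", "O")],
                    dtype=int)


def _water_partner_presence(traj, sampled, water_res, partners, dist_cutoff,
                            angle_cutoff):
    """(n_waters, n_partners, n_samples) H-bond presence, either direction."""
    top = traj.topology
    res_of = top.atom_residue_index
    out = np.zeros((len(water_res), partners.size, sampled.size), dtype=bool)
    # water can only donate to partner atoms that qualify as acceptors
    acc_ok = np.array([
        top.elements[p] == "O"
        or (str(top.resnames[p]).upper(), str(top.names[p])) in _N_ACCEPTORS
        for p in partners])
    # water as donor: water (O,H) pairs vs partner acceptors
    wd = []
    for wi, (chain, resid) in enumerate(water_res):
        atoms = top.residue_atoms(chain, resid)
        o = [i for i in atoms if top.elements[i] == "O"]
        hs = [i for i in atoms if top.elements[i] == "H"]
        wd.append((wi, o[0] if o else None, hs))
    # partner donors (for water as acceptor): partner residues' (D,H) pairs
    partner_res = {res_of[p] for p in partners}
    partner_dh = []
    all_dh = donor_hydrogen_pairs(top, Selection(water=False))
    pset = set(partners.tolist())
    for d, h in all_dh:
        if d in pset:
            partner_dh.append((d, h))
    for col, f in enumerate(sampled):
        coords = traj.coords[f]
        P = coords[partners]
        for wi, o, hs in wd:
            if o is None:
                continue
            for h in hs:
                diff = P - coords[h]
                dist = np.sqrt((diff ** 2).sum(axis=1))
                close = (dist < dist_cutoff) & acc_ok
                if close.any():
                    jj = np.nonzero(close)[0]
                    ang = angle_at(P[jj], coords[h][None, :],
                                   coords[o][None, :])
                    out[wi, jj[ang > angle_cutoff], col] = True
        if partner_dh:
            for d, h in partner_dh:
                for wi, o, hs in wd:
                    if o is None:
                        continue
                    dist = float(np.linalg.norm(coords[o] - coords[h]))
                    if dist < dist_cutoff:
                        ang = float(angle_at(coords[o], coords[h], coords[d]))
                        if ang > angle_cutoff:
                            pj = np.nonzero(partners == d)[0]
                            # water accepts from partner d: mark vs partner d
                            out[wi, pj, col] = True
    return out


def interface_water_count(traj: Trajectory, region: Selection,
                          cutoff: float = 4.0, stride: int = 1
                          ) -> tuple[np.ndarray, float, np.ndarray]:
    """Number of waters with any atom within ``cutoff`` of the region.

    Returns ``(counts per sampled frame, mean, sampled frame indices)``.
    """
    top = traj.topology
    ridx = select(top, region & Selection(water=False))
    if ridx.size == 0:
        raise ValueError("empty region")
    widx = select(top, Selection(water=True))
    if widx.size == 0:
        return (np.zeros(0, dtype=int), 0.0,
                np.arange(0, traj.n_frames, stride))
    res_of = top.atom_residue_index
    sampled = np.arange(0, traj.n_frames, stride)
    counts = np.zeros(sampled.size, dtype=int)
    for col, f in enumerate(sampled):
        if cutoff <= 0:
            counts[col] = 0
            continue
        tree = cKDTree(traj.coords[f, ridx])
        d, _ = tree.query(traj.coords[f, widx], k=1,
                          distance_upper_bound=cutoff)
        near = d < cutoff
        counts[col] = len({res_of[w] for w in widx[near]})
    return counts, float(counts.mean()) if counts.size else 0.0, sampled
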