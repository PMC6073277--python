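"""Residue contact maps and first/last-snapshot comparison statistics.

Two residues are "in contact" when their minimum inter-atomic distance
(heavy atoms by default) is below a cutoff, 4.5 A by default.  Comparing
the contact sets of an initial and a final snapshot yields two summary
statistics used to quantify how conservative an interface is:

* contact similarity — common contacts divided by the union of contacts
  of both snapshots (common + specific-to-initial + specific-to-final);
* reduction rate — (specific-to-initial − specific-to-final) divided by
  the initial contact total; positive when contacts are lost on balance,
  negative (reported signed) when the complex gains contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import Frame, Selection, Topology, Trajectory, select

__all__ = ["ContactMap", "ContactComparison", "ContactTimeline",
           "contact_map", "compare_contacts", "contact_timeline",
           "brute_force_contact_pairs"]

ResKey = tuple  # (chain, resid)


def _canonical(pair) -> tuple:
    a, b = pair
    return (a, b) if (a <= b) else (b, a)


@dataclass(frozen=True)
class ContactMap:
    pairs: frozenset            # canonicalised ((chain, resid), (chain, resid))
    time: float = 0.0
    cutoff: float = 4.5
    atom_class: str = "heavy"   # heavy | any | ca

    def __post_init__(self):
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-contact {a} is not a valid pair")

    def __len__(self):
        return len(self.pairs)


@dataclass(frozen=True)
class ContactComparison:
    n_initial: int
    n_final: int
    n_common: int
    n_specific_initial: int
    n_specific_final: int
    similarity: float
    reduction_rate: float

    def __post_init__(self):
        if self.n_initial != self.n_common + self.n_specific_initial:
            raise ValueError("initial count != common + specific-initial")
        if self.n_final != self.n_common + self.n_specific_final:
            raise ValueError("final count != common + specific-final")
        if not 0.0 <= self.similarity <= 1.0:
            raise ValueError("similarity outside [0, 1]")

    @staticmethod
    def from_counts(n_initial: int, n_final: int, n_common: int
                    ) -> "ContactComparison":
        spec_i = n_initial - n_common
        spec_f = n_final - n_common
        if min(spec_i, spec_f, n_common) < 0:
            raise ValueError("inconsistent counts")
        if n_initial == 0:
            raise ValueError("reduction rate undefined for an empty "
                             "initial contact set")
        total = n_common + spec_i + spec_f
        similarity = n_common / total if total else 1.0
        return ContactComparison(
            n_initial=n_initial, n_final=n_final, n_common=n_common,
            n_specific_initial=spec_i, n_specific_final=spec_f,
            similarity=similarity,
            reduction_rate=(spec_i - spec_f) / n_initial,
        )


def _class_indices(topology: Topology, sel: Selection, atom_class: str
                   ) -> np.ndarray:
    if atom_class == "heavy":
        sel = sel & Selection(heavy_only=True)
    elif atom_class == "ca":
        sel = sel & Selection(calpha_only=True)
    elif atom_class != "any":
        raise ValueError(f"unknown atom class {atom_class!r}")
    return select(topology, sel)


def contact_map(frame: Frame, topology: Topology, group_a: Selection,
                group_b: Selection, cutoff: float = 4.5,
                atom_class: str = "heavy",
                exclude_neighbors: bool = False) -> ContactMap:
    """Residue pairs of group A x group B with min atom distance < cutoff.

    ``exclude_neighbors`` drops same-chain pairs with |resid difference|
    <= 1 (off by default: inter-molecular maps have none).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ia = _class_indices(topology, group_a, atom_class)
    ib = _class_indices(topology, group_b, atom_class)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("empty selection for contact map")
    ta = cKDTree(frame.coords[ia])
    tb = cKDTree(frame.coords[ib])
    sparse = ta.sparse_distance_matrix(tb, cutoff, output_type="coo_matrix")
    res_of = topology.atom_residue_index
    keys = topology.residue_keys
    pairs = set()
    for i, j, d in zip(sparse.row, sparse.col, sparse.data):
        if d >= cutoff:
            continue
        ra = keys[res_of[ia[i]]]
        rb = keys[res_of[ib[j]]]
        if ra == rb:
            continue
        if exclude_neighbors and ra[0] == rb[0] and abs(ra[1] - rb[1]) <= 1:
            continue
        pairs.add(_canonical((ra, rb)))
    return ContactMap(pairs=frozenset(pairs), time=frame.time, cutoff=cutoff,
                      atom_class=atom_class)


def brute_force_contact_pairs(frame: Frame, topology: Topology,
                              group_a: Selection, group_b: Selection,
                              cutoff: float = 4.5,
                              atom_class: str = "heavy") -> frozenset:
    """Independent oracle: dense all-pairs distance scan (no spatial index)."""
    ia = _class_indices(topology, group_a, atom_class)
    ib = _class_indices(topology, group_b, atom_class)
    diff = frame.coords[ia][:, None, :] - frame.coords[ib][None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    res_of = topology.atom_residue_index
    keys = topology.residue_keys
    pairs = set()
    for i, j in np.argwhere(dist < cutoff):
        ra, rb = keys[res_of[ia[i]]], keys[res_of[ib[j]]]
        if ra != rb:
            pairs.add(_canonical((ra, rb)))
    return frozenset(pairs)


def compare_contacts(initial: ContactMap, final: ContactMap
                     ) -> ContactComparison:
    """Contact similarity and (signed) reduction rate between two maps."""
    common = initial.pairs & final.pairs
    spec_i = initial.pairs - final.pairs
    spec_f = final.pairs - initial.pairs
    if len(initial.pairs) == 0:
        raise ValueError("reduction rate undefined for an empty initial map")
    total = len(common) + len(spec_i) + len(spec_f)
    return ContactComparison(
        n_initial=len(initial.pairs),
        n_final=len(final.pairs),
        n_common=len(common),
        n_specific_initial=len(spec_i),
        n_specific_final=len(spec_f),
        similarity=len(common) / total,
        reduction_rate=(len(spec_i) - len(spec_f)) / len(initial.pairs),
    )


@dataclass
class ContactTimeline:
    pairs: list                     # canonical residue pairs
    frames: np.ndarray              # sampled frame indices
    presence: np.ndarray            # bool, (n_pairs, n_samples)
    occupancy: np.ndarray           # fraction per pair
    break_frame: list               # first sampled frame index after which the
                                    # pair stays absent; None if never broken


def contact_timeline(traj: Trajectory, group_a: Selection,
                     group_b: Selection, cutoff: float = 4.5,
                     stride: int = 1, atom_class: str = "heavy"
                     ) -> ContactTimeline:
    """Track every contact pair ever observed across sampled frames."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    sampled = np.arange(0, traj.n_frames, stride)
    maps = [contact_map(traj.frame(int(f)), traj.topology, group_a, group_b,
                        cutoff=cutoff, atom_class=atom_class)
            for f in sampled]
    all_pairs = sorted(set().union(*(m.pairs for m in maps)))
    presence = np.zeros((len(all_pairs), len(sampled)), dtype=bool)
    index = {p: i for i, p in enumerate(all_pairs)}
    for col, m in enumerate(maps):
        for p in m.pairs:
            presence[index[p], col] = True
    occupancy = presence.mean(axis=1) if len(sampled) else np.zeros(0)
    breaks = []
    for row in presence:
        if row[-1]:
            breaks.append(None)
        else:
            # last True position + 1 sampled step; all-absent pairs impossible
            last_true = np.flatnonzero(row).max()
            breaks.append(int(sampled[last_true + 1]))
    return ContactTimeline(pairs=all_pairs, frames=sampled, presence=presence,
                           occupancy=occupancy, break_frame=breaks)
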