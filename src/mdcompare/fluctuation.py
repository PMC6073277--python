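"""Superposition-based mobility metrics.

RMSD here is the plain coordinate root-mean-square deviation after an
optimal (Kabsch) superposition, RMSD = sqrt((1/N) sum_i delta_i^2); RMSF
is the per-atom root-mean-square fluctuation about the iterated mean
structure, convertible to a crystallographic isotropic B-factor through
B = (8 pi^2 / 3) <dr^2>.  The superposition itself is delegated to
scipy's weighted Wahba solver (reflections excluded).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation
from scipy import stats

from .core import Frame, Selection, Topology, Trajectory, select
from .geometry import dihedral

__all__ = [
    "SuperpositionResult", "FluctuationProfile", "DihedralSeries",
    "kabsch_superpose", "apply_superposition", "superpose_frames",
    "rmsd_series", "rmsf", "windowed_rmsf", "bfactor_correlation",
    "radius_of_gyration", "dihedral_series", "BFACTOR_PER_MSF",
]

#: B = (8 pi^2 / 3) <dr^2>; this is 8 pi^2 / 3.
BFACTOR_PER_MSF = 8.0 * np.pi ** 2 / 3.0


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray      # 3x3 proper rotation
    translation: np.ndarray   # 3-vector, A
    rmsd: float               # A

    def __post_init__(self):
        R = np.asarray(self.rotation)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("reflection is not a valid superposition")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")


@dataclass
class FluctuationProfile:
    residue_labels: list
    rmsf: np.ndarray            # per residue, A
    bfactor: np.ndarray         # per residue, A^2, = BFACTOR_PER_MSF * rmsf^2
    atom_indices: np.ndarray
    atom_rmsf: np.ndarray
    residue_keys: list
    window: Optional[tuple] = None   # (start_frame, end_frame) when windowed


@dataclass
class DihedralSeries:
    label: str
    chain: str
    resid: int
    phi: Optional[np.ndarray]   # degrees in (-180, 180]; None at N-terminus
    psi: Optional[np.ndarray]   # None at C-terminus


def _check_nondegenerate(points: np.ndarray) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-10 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear or coincident) point set")


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: Optional[np.ndarray] = None
                     ) -> SuperpositionResult:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation R and translation t minimising the
    (weighted) RMSD of ``R @ x + t`` against the reference, and the
    minimised RMSD itself.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"point-count mismatch: {mobile.shape} vs "
                         f"{reference.shape}")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 points to superpose")
    _check_nondegenerate(reference)
    _check_nondegenerate(mobile)
    if weights is None:
        w = np.ones(mobile.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (mobile.shape[0],) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be a nonnegative per-atom vector")
    wsum = w.sum()
    mob_c = (w[:, None] * mobile).sum(axis=0) / wsum
    ref_c = (w[:, None] * reference).sum(axis=0) / wsum
    rot, _ = Rotation.align_vectors(reference - ref_c, mobile - mob_c,
                                    weights=w)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    moved = mobile @ R.T + t
    delta2 = ((moved - reference) ** 2).sum(axis=1)
    rmsd = float(np.sqrt((w * delta2).sum() / wsum))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def apply_superposition(coords: np.ndarray, res: SuperpositionResult
                        ) -> np.ndarray:
    return coords @ res.rotation.T + res.translation


def superpose_frames(traj: Trajectory, sel: Selection,
                     ref_mode: str = "mean", tol: float = 1e-6,
                     max_iter: int = 10,
                     window: Optional[tuple] = None) -> np.ndarray:
    """Superpose all (window) frames over ``sel``; returns aligned selected
    coordinates of shape (n_frames, n_sel, 3).

    ``ref_mode='mean'`` iterates superpose -> re-average until the mean
    structure moves less than ``tol`` A; ``'first'`` fits to frame 1.
    """
    idx = select(traj, sel)
    if idx.size == 0:
        raise ValueError("empty selection")
    lo, hi = (0, traj.n_frames) if window is None else window
    if not (0 <= lo < hi <= traj.n_frames):
        raise ValueError(f"window {window} outside trajectory "
                         f"of {traj.n_frames} frames")
    X = traj.coords[lo:hi, idx, :]
    ref = X[0]
    n_pass = 1 if ref_mode == "first" else max_iter
    aligned = X
    for _ in range(n_pass):
        aligned = np.empty_like(X)
        for f in range(X.shape[0]):
            sp = kabsch_superpose(X[f], ref)
            aligned[f] = apply_superposition(X[f], sp)
        if ref_mode == "first":
            break
        new_ref = aligned.mean(axis=0)
        shift = float(np.abs(new_ref - ref).max())
        ref = new_ref
        if shift < tol:
            break
    return aligned


def rmsd_series(traj: Trajectory, sel: Selection, reference: Frame
                ) -> np.ndarray:
    """Per-frame RMSD (A) against a reference frame over the selection.

    Each frame is independently superposed onto the reference before the
    deviation is evaluated on the same selection.
    """
    idx = select(traj, sel)
    if idx.size == 0:
        raise ValueError("empty selection")
    ref = reference.coords[idx]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        out[f] = kabsch_superpose(traj.coords[f, idx], ref).rmsd
    return out


def _residue_aggregate(topology: Topology, idx: np.ndarray,
                       atom_msf: np.ndarray):
    res_of = topology.atom_residue_index[idx]
    keys = []
    msf = []
    for r in sorted(set(res_of.tolist())):
        keys.append(r)
        msf.append(atom_msf[res_of == r].mean())
    return np.array(keys), np.sqrt(np.array(msf))


def rmsf(traj: Trajectory, sel: Selection, window: Optional[tuple] = None,
         ref_mode: str = "mean") -> FluctuationProfile:
    """Per-residue RMSF about the (iterated) mean structure, plus B-factors."""
    lo, hi = (0, traj.n_frames) if window is None else window
    if hi - lo < 2:
        raise ValueError("need at least 2 frames for a fluctuation")
    aligned = superpose_frames(traj, sel, ref_mode=ref_mode, window=(lo, hi))
    idx = select(traj, sel)
    mean = aligned.mean(axis=0)
    atom_msf = ((aligned - mean) ** 2).sum(axis=2).mean(axis=0)
    res_idx, res_rmsf = _residue_aggregate(traj.topology, idx, atom_msf)
    labels = [traj.topology.residue_label(int(r)) for r in res_idx]
    keys = [traj.topology.residue_keys[int(r)] for r in res_idx]
    return FluctuationProfile(
        residue_labels=labels,
        rmsf=res_rmsf,
        bfactor=BFACTOR_PER_MSF * res_rmsf ** 2,
        atom_indices=idx,
        atom_rmsf=np.sqrt(atom_msf),
        residue_keys=keys,
        window=None if window is None else (lo, hi),
    )


def windowed_rmsf(traj: Trajectory, sel: Selection, window_len: int,
                  stride: int) -> tuple[np.ndarray, list, list]:
    """Sliding-window RMSF: (residues x windows) matrix for heat maps.

    Returns ``(matrix, residue_labels, window_ranges)``.
    """
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    if window_len > traj.n_frames:
        raise ValueError("window_len exceeds trajectory length")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    starts = list(range(0, traj.n_frames - window_len + 1, stride))
    cols = []
    labels = None
    ranges = []
    for s in starts:
        prof = rmsf(traj, sel, window=(s, s + window_len))
        cols.append(prof.rmsf)
        labels = prof.residue_labels
        ranges.append((s, s + window_len))
    return np.column_stack(cols), labels, ranges


def bfactor_correlation(profile: FluctuationProfile, topology: Topology
                        ) -> tuple[float, int, float]:
    """OLS R^2 between computed and experimental per-residue B-factors.

    The experimental per-residue value is the mean over the profile's atoms
    in that residue (the C-alpha value when the profile is C-alpha-only).
    Returns ``(r_squared, n, slope)`` — R^2 is sign-blind, so the slope is
    reported alongside.
    """
    res_of = topology.atom_residue_index[profile.atom_indices]
    bexp_atoms = topology.bfactors_exp[profile.atom_indices]
    computed, experimental = [], []
    order = {tuple(k): i for i, k in enumerate(profile.residue_keys)}
    for r in sorted(set(res_of.tolist())):
        key = tuple(topology.residue_keys[r])
        vals = bexp_atoms[res_of == r]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        computed.append(profile.bfactor[order[key]])
        experimental.append(vals.mean())
    n = len(computed)
    if n < 3:
        raise ValueError(f"only {n} residues have experimental B-factors; "
                         "need at least 3")
    res = stats.linregress(np.array(computed), np.array(experimental))
    return float(res.rvalue ** 2), n, float(res.slope)


def radius_of_gyration(traj: Trajectory, sel: Selection) -> np.ndarray:
    """Mass-weighted radius of gyration per frame (A)."""
    idx = select(traj, sel)
    if idx.size == 0:
        raise ValueError("empty selection")
    m = traj.topology.masses[idx]
    X = traj.coords[:, idx, :]
    com = (m[None, :, None] * X).sum(axis=1) / m.sum()
    d2 = ((X - com[:, None, :]) ** 2).sum(axis=2)
    return np.sqrt((m[None, :] * d2).sum(axis=1) / m.sum())


def dihedral_series(traj: Trajectory, residues: Selection
                    ) -> list[DihedralSeries]:
    """Backbone phi/psi time series for the selected residues.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1).
    Chain-terminal residues have the corresponding angle set to ``None``.
    """
    top = traj.topology
    idx = select(traj, residues)
    res_set = sorted(set(top.atom_residue_index[idx].tolist()))

    def atom_of(chain, resid, name):
        try:
            ats = top.residue_atoms(chain, resid)
        except KeyError:
            return None
        hit = ats[top.names[ats] == name]
        return int(hit[0]) if hit.size else None

    out = []
    for r in res_set:
        chain, resid = top.residue_keys[r]
        n_i = atom_of(chain, resid, "N")
        ca_i = atom_of(chain, resid, "CA")
        c_i = atom_of(chain, resid, "C")
        if None in (n_i, ca_i, c_i):
            continue  # not a peptide residue
        c_prev = atom_of(chain, resid - 1, "C")
        n_next = atom_of(chain, resid + 1, "N")
        phi = None
        psi = None
        if c_prev is not None:
            phi = dihedral(traj.coords[:, c_prev], traj.coords[:, n_i],
                           traj.coords[:, ca_i], traj.coords[:, c_i])
        if n_next is not None:
            psi = dihedral(traj.coords[:, n_i], traj.coords[:, ca_i],
                           traj.coords[:, c_i], traj.coords[:, n_next])
        out.append(DihedralSeries(label=top.residue_label(r), chain=chain,
                                  resid=resid, phi=phi, psi=psi))
    return out
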