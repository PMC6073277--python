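"""Cartesian PCA, free-energy landscapes, and conformational clustering.

The free-energy landscape maps the 2D histogram of (PC1, PC2) projections
to Gibbs energies via dG(X) = -k_B T ln P(X), anchored so that the most
populated bin sits at zero.  Basins are local minima of the smoothed
landscape that lie within a configurable depth above the global minimum
(default one k_B T): the relatively independent low-free-energy regions
of the surface.

Clustering follows the classic RMSD-threshold scheme: frames whose
pairwise superposed C-alpha RMSD falls below the threshold (default
1.7 A) belong to one cluster.  A deterministic leader pass in time order
assigns frames, then each cluster's representative is refined to its
medoid (minimal mean RMSD to its members).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .core import Selection, Trajectory, select
from .fluctuation import superpose_frames

__all__ = ["PCAModes", "FELGrid", "ClusterResult", "pca",
           "free_energy_landscape", "cluster", "cluster_from_matrix",
           "cluster_complete_linkage", "slow_mode_arrows",
           "pairwise_rmsd_matrix", "KB_KCAL"]

#: Boltzmann constant, kcal/(mol K)
KB_KCAL = 1.987e-3

CLUSTER_THRESHOLD = 1.7   # A (0.17 nm)


@dataclass
class PCAModes:
    mean_structure: np.ndarray     # (n_sel, 3), A
    eigenvectors: np.ndarray       # (3n, 3n), columns, orthonormal
    eigenvalues: np.ndarray        # (3n,), A^2, descending, >= 0
    projections: np.ndarray        # (n_frames, 3n), centred
    atom_indices: np.ndarray

    def explained_variance_ratio(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else self.eigenvalues


@dataclass
class FELGrid:
    pc1_edges: np.ndarray
    pc2_edges: np.ndarray
    probability: np.ndarray        # (n_bins, n_bins), sums to 1
    delta_g: np.ndarray            # kcal/mol, NaN on empty bins, min 0
    temperature: float
    kb: float
    n_basins: int
    basin_depth: float             # kcal/mol threshold used for basin count


@dataclass
class ClusterResult:
    labels: np.ndarray             # per sampled frame
    representatives: list          # sampled-frame position of each medoid
    populations: np.ndarray        # fraction per cluster
    threshold: float
    sampled_frames: np.ndarray     # original frame indices

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def pca(traj: Trajectory, sel: Selection) -> PCAModes:
    """Principal components of the superposed selected coordinates."""
    if traj.n_frames < 3:
        raise ValueError("PCA needs at least 3 frames")
    aligned = superpose_frames(traj, sel)
    idx = select(traj, sel)
    F = aligned.shape[0]
    X = aligned.reshape(F, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (F - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    return PCAModes(mean_structure=mean.reshape(-1, 3),
                    eigenvectors=evecs, eigenvalues=evals,
                    projections=Xc @ evecs, atom_indices=idx)


def free_energy_landscape(modes: PCAModes, temperature: float = 300.0,
                          n_bins: int = 50,
                          basin_depth_kt: float = 1.0) -> FELGrid:
    """dG(X) = -k_B T ln P(X) over the (PC1, PC2) histogram."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    p1 = modes.projections[:, 0]
    p2 = modes.projections[:, 1]
    hist, xe, ye = np.histogram2d(p1, p2, bins=n_bins)
    prob = hist / hist.sum()
    kbt = KB_KCAL * temperature
    with np.errstate(divide="ignore"):
        dg = np.where(prob > 0, -kbt * np.log(prob), np.nan)
    dg = dg - np.nanmin(dg)
    depth = basin_depth_kt * kbt
    n_basins = _count_basins(prob, basin_depth_kt)
    return FELGrid(pc1_edges=xe, pc2_edges=ye, probability=prob,
                   delta_g=dg, temperature=temperature, kb=KB_KCAL,
                   n_basins=n_basins, basin_depth=depth)


def _count_basins(prob: np.ndarray, depth_kt: float,
                  smooth_sigma: float = 1.5) -> int:
    """Distinct low-free-energy regions of the smoothed landscape.

    The probability surface is Gaussian-smoothed (sigma in bins) and a
    basin is a connected component of bins within ``depth_kt`` k_BT of the
    deepest one, i.e. with smoothed probability >= P_max * exp(-depth_kt).
    Smoothing the counts (rather than the log-transformed energies) keeps
    shot noise in sparsely populated bins from fragmenting one basin into
    many; each well-separated minimum still contributes one component.
    """
    smooth = ndimage.gaussian_filter(prob, smooth_sigma, mode="constant")
    low = smooth >= smooth.max() * np.exp(-depth_kt)
    # 8-connectivity: diagonal neighbours belong to the same basin
    _, n = ndimage.label(low, structure=np.ones((3, 3), dtype=int))
    return int(n)


def pairwise_rmsd_matrix(coords: np.ndarray) -> np.ndarray:
    """All-pairs minimal (superposed) RMSD of coordinate sets (K, n, 3).

    Batched Kabsch via 3x3 SVDs; reflections are excluded by correcting
    the determinant sign, so values are true rotational best fits.
    """
    K, n, _ = coords.shape
    centred = coords - coords.mean(axis=1, keepdims=True)
    msd_self = (centred ** 2).sum(axis=(1, 2))  # per-structure sum of squares
    out = np.zeros((K, K))
    ii, jj = np.triu_indices(K, k=1)
    # covariance matrices for all pairs, in manageable blocks
    block = 200_000
    for s in range(0, ii.size, block):
        bi, bj = ii[s:s + block], jj[s:s + block]
        H = np.einsum("kni,knj->kij", centred[bi], centred[bj])
        U, S, Vt = np.linalg.svd(H)
        sign = np.sign(np.linalg.det(np.einsum("kij,kjl->kil", U, Vt)))
        S[:, -1] *= sign
        # E = sum|x|^2 + sum|y|^2 - 2 * trace(Sigma)
        e = msd_self[bi] + msd_self[bj] - 2.0 * S.sum(axis=1)
        rmsd = np.sqrt(np.maximum(e, 0.0) / n)
        out[bi, bj] = rmsd
        out[bj, bi] = rmsd
    return out


def cluster(traj: Trajectory, sel: Selection,
            threshold: float = CLUSTER_THRESHOLD,
            stride: int = 1, refine_medoid: bool = True) -> ClusterResult:
    """RMSD-threshold clustering of sampled frames.

    Frames are processed in time order and joined to the first cluster
    whose representative lies within ``threshold`` (leader algorithm);
    afterwards each representative is moved to the cluster medoid.  Every
    frame is within ``threshold`` of its representative at assignment.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    sampled = np.arange(0, traj.n_frames, stride)
    if sampled.size == 0:
        raise ValueError("stride too large: no sampled frames")
    idx = select(traj, sel)
    if idx.size == 0:
        raise ValueError("empty selection")
    coords = traj.coords[sampled][:, idx, :]
    if refine_medoid:
        D = pairwise_rmsd_matrix(coords)
        return cluster_from_matrix(D, threshold, sampled_frames=sampled,
                                   refine_medoid=True)
    # lazy leader pass: only frame-vs-representative distances are needed,
    # which keeps long trajectories O(K * n_clusters) instead of O(K^2)
    centred = coords - coords.mean(axis=1, keepdims=True)
    msd_self = (centred ** 2).sum(axis=(1, 2))
    n = coords.shape[1]

    def rmsd_pair(i, j):
        H = centred[i].T @ centred[j]
        s = np.linalg.svd(H, compute_uv=False)
        det = np.linalg.det(H)
        trace = s[0] + s[1] + (s[2] if det >= 0 else -s[2])
        e = msd_self[i] + msd_self[j] - 2.0 * trace
        return np.sqrt(max(e, 0.0) / n)

    K = coords.shape[0]
    labels = np.full(K, -1, dtype=int)
    reps: list[int] = []
    for f in range(K):
        for c, rep in enumerate(reps):
            if rmsd_pair(f, rep) <= threshold:
                labels[f] = c
                break
        else:
            labels[f] = len(reps)
            reps.append(f)
    counts = np.bincount(labels, minlength=len(reps))
    return ClusterResult(labels=labels, representatives=reps,
                         populations=counts / K, threshold=threshold,
                         sampled_frames=sampled)


def cluster_from_matrix(D: np.ndarray, threshold: float,
                        sampled_frames: Optional[np.ndarray] = None,
                        refine_medoid: bool = True) -> ClusterResult:
    """Leader + medoid clustering on a precomputed RMSD matrix.

    Useful for sweeping a threshold ladder over one distance matrix.
    """
    K = D.shape[0]
    if sampled_frames is None:
        sampled_frames = np.arange(K)
    labels = np.full(K, -1, dtype=int)
    reps: list[int] = []
    for f in range(K):
        for c, rep in enumerate(reps):
            if D[f, rep] <= threshold:
                labels[f] = c
                break
        else:
            labels[f] = len(reps)
            reps.append(f)
    if refine_medoid:
        for c in range(len(reps)):
            members = np.flatnonzero(labels == c)
            sub = D[np.ix_(members, members)]
            reps[c] = int(members[np.argmin(sub.mean(axis=1))])
    counts = np.bincount(labels, minlength=len(reps))
    return ClusterResult(labels=labels, representatives=reps,
                         populations=counts / K, threshold=threshold,
                         sampled_frames=sampled_frames)


def cluster_complete_linkage(D: np.ndarray, threshold: float) -> np.ndarray:
    """Exact complete-linkage partition of a distance matrix at a threshold.

    Greedy agglomeration by smallest maximal inter-cluster distance; O(N^3),
    intended for small frame counts where an exact partition is wanted
    (every within-cluster pair is then guaranteed below the threshold).
    Returns per-item labels.
    """
    K = D.shape[0]
    clusters: list[list[int]] = [[i] for i in range(K)]
    while len(clusters) > 1:
        best, best_d = None, np.inf
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = D[np.ix_(clusters[a], clusters[b])].max()
                if d < best_d:
                    best_d, best = d, (a, b)
        if best_d > threshold:
            break
        a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(K, dtype=int)
    for c, members in enumerate(clusters):
        labels[members] = c
    return labels


def slow_mode_arrows(modes: PCAModes, mode_index: int = 0,
                     scale: float = 1.0) -> np.ndarray:
    """Per-atom displacement arrows of one mode (porcupine-plot vectors).

    vectors = eigenvector components * sqrt(eigenvalue) * scale, anchored
    at the mean structure.
    """
    if not 0 <= mode_index < modes.eigenvalues.size:
        raise IndexError(f"mode index {mode_index} out of range")
    vec = modes.eigenvectors[:, mode_index].reshape(-1, 3)
    return vec * np.sqrt(modes.eigenvalues[mode_index]) * scale
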