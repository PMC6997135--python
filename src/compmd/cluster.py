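"""RMSD-threshold conformational clustering and time-dependent cluster growth.

Two frames are linked when their pairwise superposed RMSD is at or below a
threshold (the pairwise indicator C = 1 iff ΔRMSD ≤ threshold).  The
indicator alone is not transitive, so it does not define a partition; here
clusters are the connected components of the indicator graph — single-linkage
at the threshold — which is the minimal completion of the pairwise rule.
Preset thresholds: 2.4 Å for a coarse partition, 1.5 Å for fine
time-dependent cluster counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import SelectionError
from .geometry import _batch_rmsd
from .traj_io import Trajectory

__all__ = [
    "COARSE_THRESHOLD",
    "FINE_THRESHOLD",
    "ClusterAssignment",
    "pairwise_rmsd_matrix",
    "threshold_cluster",
    "cluster_growth",
]

COARSE_THRESHOLD = 2.4   # Å
FINE_THRESHOLD = 1.5     # Å


@dataclass
class ClusterAssignment:
    labels: np.ndarray          # per-frame cluster id, 0-based
    threshold: float            # Å
    representatives: np.ndarray  # per-cluster frame index
    occupancy: np.ndarray       # per-cluster fraction, sums to 1
    indicator: np.ndarray       # boolean pair matrix: same-cluster edge

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def pairwise_rmsd_matrix(traj: Trajectory, sel=None) -> np.ndarray:
    """Symmetric matrix of superposed RMSD between all frame pairs (Å)."""
    if traj.n_frames < 2:
        raise ValueError("pairwise RMSD needs at least 2 frames")
    sel = np.arange(traj.n_atoms) if sel is None else np.asarray(sel, int)
    if sel.size == 0:
        raise SelectionError("empty atom selection")
    n = traj.n_frames
    matrix = np.zeros((n, n))
    for i in range(n - 1):
        row = _batch_rmsd(traj.xyz[i + 1:], traj.xyz[i], sel)
        matrix[i, i + 1:] = row
        matrix[i + 1:, i] = row
    return matrix


def threshold_cluster(matrix: np.ndarray, threshold: float = COARSE_THRESHOLD,
                      energies=None) -> ClusterAssignment:
    """Cluster frames as connected components of the ≤-threshold graph.

    Cluster ids are ordered by first-occurring frame.  The representative of
    a cluster is its lowest-energy member when per-frame ``energies`` are
    supplied (matching the lowest-energy-conformation convention), otherwise
    the medoid (minimum mean RMSD to the other members); ties go to the
    earliest frame.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("RMSD matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-9):
        raise ValueError("RMSD matrix must be symmetric")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    n = matrix.shape[0]
    indicator = matrix <= threshold
    _, raw = connected_components(csr_matrix(indicator), directed=False)

    # relabel so cluster ids follow the first frame of each component
    order = {}
    labels = np.empty(n, dtype=int)
    for frame, component in enumerate(raw):
        if component not in order:
            order[component] = len(order)
        labels[frame] = order[component]
    n_clusters = len(order)

    representatives = np.empty(n_clusters, dtype=int)
    occupancy = np.empty(n_clusters)
    if energies is not None:
        energies = np.asarray(energies, dtype=float)
        if energies.shape != (n,):
            raise ValueError("energies must have one value per frame")
    for c in range(n_clusters):
        members = np.flatnonzero(labels == c)
        occupancy[c] = members.size / n
        if energies is not None:
            representatives[c] = members[np.argmin(energies[members])]
        elif members.size == 1:
            representatives[c] = members[0]
        else:
            mean_rmsd = matrix[np.ix_(members, members)].mean(axis=1)
            representatives[c] = members[np.argmin(mean_rmsd)]
    return ClusterAssignment(labels=labels, threshold=float(threshold),
                             representatives=representatives,
                             occupancy=occupancy, indicator=indicator)


def cluster_growth(traj: Trajectory, sel=None,
                   threshold: float = FINE_THRESHOLD,
                   stride: int = 1,
                   matrix: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative cluster count over growing trajectory prefixes.

    Returns ``(prefix_lengths, counts)`` where ``counts[k]`` is the number of
    clusters found on the first ``prefix_lengths[k]`` frames (every
    ``stride`` frames, always ending at the full trajectory).  A plateau in
    the curve signals converged conformational sampling.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if matrix is None:
        matrix = pairwise_rmsd_matrix(traj, sel)
    n = matrix.shape[0]
    prefixes = list(range(stride, n + 1, stride))
    if not prefixes or prefixes[-1] != n:
        prefixes.append(n)
    counts = np.empty(len(prefixes), dtype=int)
    adjacency = matrix <= threshold
    for k, m in enumerate(prefixes):
        counts[k], _ = connected_components(
            csr_matrix(adjacency[:m, :m]), directed=False)
    return np.asarray(prefixes), counts
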