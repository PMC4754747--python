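"""Conformational clustering by pairwise Cα RMSD.

Pairwise Kabsch-optimal RMSD over all frame pairs, greedy neighbor-count
(GROMOS-style) clustering at a cutoff, and the cutoff-selection rule: the
smallest cutoff on a grid at which the top 8 clusters jointly cover more
than 90% of the frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TrajectoryEnsemble, ValidationError


def pairwise_rmsd_matrix(
    traj: TrajectoryEnsemble, selection: str = "calpha"
) -> np.ndarray:
    """F x F matrix of Kabsch-optimal RMSD (Angstrom) between all frame
    pairs, computed from batched 3x3 cross-covariance SVDs."""
    if traj.n_frames < 2:
        raise ValidationError("need at least 2 frames")
    from .core import select as _select

    sel = _select(traj.model, selection)
    coords = traj.frames[:, sel]  # F x N x 3
    f, n, _ = coords.shape
    centered = coords - coords.mean(axis=1, keepdims=True)
    sq = np.einsum("fij,fij->f", centered, centered)  # sum of squares per frame
    ii, jj = np.triu_indices(f, k=1)
    # Cross-covariance 3x3 for every pair, then the optimal-superposition
    # identity rmsd^2 = (|P|^2 + |Q|^2 - 2(s1 + s2 +/- s3)) / N.
    cross = np.einsum("paj,pak->pjk", centered[ii], centered[jj])
    u, s, vt = np.linalg.svd(cross)
    det = np.linalg.det(u) * np.linalg.det(vt)
    traces = s[:, 0] + s[:, 1] + np.sign(det) * s[:, 2]
    msd = np.maximum(0.0, (sq[ii] + sq[jj] - 2.0 * traces) / n)
    # the identity cancels large sums; values at the cancellation floor are
    # exact zeros (identical frames up to rigid motion)
    floor = 64.0 * np.finfo(float).eps * (sq[ii] + sq[jj]) / n
    msd = np.where(msd < floor, 0.0, msd)
    matrix = np.zeros((f, f))
    matrix[ii, jj] = np.sqrt(msd)
    matrix[jj, ii] = matrix[ii, jj]
    return matrix


@dataclass
class ClusterResult:
    cutoff: float  # Angstrom
    clusters: list  # frame-label lists, largest first
    representatives: list  # one frame label per cluster
    coverage_top8: float

    @property
    def sizes(self) -> list:
        return [len(c) for c in self.clusters]


def gromos_cluster(
    matrix: np.ndarray,
    cutoff: float,
    frame_labels: np.ndarray | None = None,
    top_n: int = 8,
) -> ClusterResult:
    """Greedy neighbor-count clustering.

    Repeatedly seed a cluster at the unassigned frame with the most
    unassigned neighbors within ``cutoff`` (ties broken toward the lowest
    frame label), assign the seed and those neighbors, and remove them.
    Each cluster's representative is the member with the smallest mean RMSD
    to the rest of its cluster (ties toward the lowest label).  Clusters are
    ordered by decreasing size, ties toward earlier formation.
    """
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    matrix = np.asarray(matrix, dtype=float)
    f = matrix.shape[0]
    labels = (
        np.arange(f) if frame_labels is None else np.asarray(frame_labels, dtype=int)
    )
    neighbors = matrix < cutoff
    np.fill_diagonal(neighbors, False)
    remaining = np.ones(f, dtype=bool)
    raw_clusters: list[np.ndarray] = []
    while remaining.any():
        counts = (neighbors & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        seed = int(np.argmax(counts))  # first maximum = lowest frame index
        members = np.where(remaining & (neighbors[seed] | (np.arange(f) == seed)))[0]
        raw_clusters.append(members)
        remaining[members] = False
    order = sorted(range(len(raw_clusters)), key=lambda i: (-len(raw_clusters[i]), i))
    clusters = []
    representatives = []
    for i in order:
        members = raw_clusters[i]
        if len(members) == 1:
            rep = members[0]
        else:
            sub = matrix[np.ix_(members, members)]
            mean_rmsd = sub.sum(axis=1) / (len(members) - 1)
            rep = members[int(np.argmin(mean_rmsd))]
        clusters.append([int(labels[m]) for m in members])
        representatives.append(int(labels[rep]))
    top = sum(len(c) for c in clusters[:top_n])
    return ClusterResult(
        cutoff=float(cutoff),
        clusters=clusters,
        representatives=representatives,
        coverage_top8=top / f,
    )


def select_cutoff(
    matrix: np.ndarray,
    top_n: int = 8,
    coverage: float = 0.90,
    grid_step: float = 0.1,
    frame_labels: np.ndarray | None = None,
) -> ClusterResult:
    """Scan cutoffs upward from ``grid_step`` in steps of ``grid_step`` and
    return the clustering at the smallest cutoff whose top-``top_n``
    clusters cover more than ``coverage`` of the frames."""
    if grid_step <= 0:
        raise ValidationError("grid step must be positive")
    max_needed = float(np.max(matrix)) + grid_step
    cutoff = grid_step
    while cutoff <= max_needed + 1e-9:
        result = gromos_cluster(matrix, cutoff, frame_labels=frame_labels, top_n=top_n)
        if result.coverage_top8 > coverage:
            return result
        cutoff += grid_step
    raise ValidationError(
        f"no cutoff on the grid reaches top-{top_n} coverage > {coverage}"
    )


def coverage_curve(
    matrix: np.ndarray, cutoffs: np.ndarray, top_n: int = 8
) -> np.ndarray:
    """Top-``top_n`` coverage at each cutoff (diagnostic for the scan)."""
    return np.array(
        [gromos_cluster(matrix, c, top_n=top_n).coverage_top8 for c in cutoffs]
    )
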