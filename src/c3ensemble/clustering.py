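"""GROMOS-style (Daura) neighbor-count conformational clustering.

Greedy scheme on a pairwise minimized-RMSD matrix: the frame with the most
neighbors within the cutoff (ties to the lowest frame index) seeds each
cluster, it and its neighbors are removed, and the count repeats on the
remainder.  The neighbor count includes the candidate itself, so a cluster's
size equals its center's neighbor count at the time of selection and cluster
sizes are non-increasing.

Coverage is the cumulative fraction of frames captured by the top-k
clusters; ``cutoff_for_coverage`` calibrates the cutoff on a grid so a
coverage target is met within a cluster budget (e.g. 85% within six
clusters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EnsembleTrajectory

__all__ = [
    "ClusterResult",
    "pairwise_rmsd_matrix",
    "daura_cluster",
    "concatenate_monomers",
    "cutoff_for_coverage",
]

#: Default backbone atom names for clustering selections.  Configurable:
#: Cbeta is included alongside the backbone proper to weight sidechain
#: direction, and the amide proton where present.
BACKBONE_ATOMS = ("N", "CA", "CB", "C", "O", "H")


@dataclass
class ClusterResult:
    """Daura clustering outcome at a fixed cutoff.

    ``clusters`` is ordered by size descending (ties: center index
    ascending); clusters are disjoint and exhaustive over the frames.
    """

    cutoff: float
    clusters: list[tuple[int, np.ndarray]]
    coverage_curve: np.ndarray
    n_frames: int
    selection: str = ""
    concatenated: bool = False

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(m) for _, m in self.clusters])

    @property
    def populations(self) -> np.ndarray:
        return self.sizes / self.n_frames

    def coverage(self, max_clusters: int) -> float:
        k = min(max_clusters, len(self.clusters))
        return float(self.coverage_curve[k - 1])

    def membership_table(self) -> pd.DataFrame:
        rows = []
        for cid, (center, members) in enumerate(self.clusters):
            for fr in members:
                rows.append((cid, int(center), int(fr)))
        return pd.DataFrame(rows, columns=["cluster_id", "center_frame", "frame"])

    def cluster_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster_id": np.arange(len(self.clusters)),
                "center_frame": [int(c) for c, _ in self.clusters],
                "size": self.sizes,
                "population_fraction": self.populations,
            }
        )


def pairwise_rmsd_matrix(
    traj: EnsembleTrajectory, selection: np.ndarray | None = None
) -> np.ndarray:
    """Symmetric matrix of minimized superposition RMSDs between frames."""
    if traj.n_frames < 2:
        raise ValueError("pairwise RMSD needs at least 2 frames")
    idx = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    x = traj.coords[:, idx, :].astype(float)
    n, a, _ = x.shape
    if a < 3:
        raise ValueError("selection must contain at least 3 atoms")
    centered = x - x.mean(axis=1, keepdims=True)
    gram = np.einsum("nij,nij->n", centered, centered)
    mat = np.zeros((n, n))
    for i in range(n - 1):
        xi = centered[i]
        for j in range(i + 1, n):
            h = xi.T @ centered[j]
            s = np.linalg.svd(h, compute_uv=False)
            d = s[0] + s[1] + np.sign(np.linalg.det(h)) * s[2]
            msd = max((gram[i] + gram[j] - 2.0 * d) / a, 0.0)
            mat[i, j] = mat[j, i] = np.sqrt(msd)
    return mat


def daura_cluster(matrix: np.ndarray, cutoff: float) -> ClusterResult:
    """Cluster a pairwise RMSD matrix with the greedy neighbor-count scheme."""
    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("matrix must be square")
    if np.isnan(mat).any():
        raise ValueError("matrix contains NaNs")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    n = mat.shape[0]
    adjacency = mat <= cutoff
    unassigned = np.ones(n, dtype=bool)
    clusters: list[tuple[int, np.ndarray]] = []
    while unassigned.any():
        live = np.nonzero(unassigned)[0]
        counts = adjacency[np.ix_(live, live)].sum(axis=1)
        center = live[int(np.argmax(counts))]  # argmax -> lowest index on ties
        members = live[adjacency[center, live]]
        clusters.append((int(center), members))
        unassigned[members] = False
    clusters.sort(key=lambda c: (-len(c[1]), c[0]))
    sizes = np.array([len(m) for _, m in clusters])
    coverage_curve = np.cumsum(sizes) / n
    return ClusterResult(
        cutoff=float(cutoff),
        clusters=clusters,
        coverage_curve=coverage_curve,
        n_frames=n,
    )


def concatenate_monomers(
    traj: EnsembleTrajectory, selection: np.ndarray | None = None
) -> tuple[EnsembleTrajectory, pd.DataFrame]:
    """Concatenate the three monomers into a single-monomer pseudo-trajectory.

    Frames are ordered monomer A first, then B, then C; provenance records
    ``(monomer, source_frame)`` per pseudo-frame.  The monomers must share
    an identical (residue_number, atom_name) sequence over the selection.
    """
    idx_all = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    labels = traj.monomer_ids[:3]
    if len(labels) < 3:
        raise ValueError("trimer concatenation needs three monomers")
    per_mono = []
    keys = []
    for m in labels:
        sub = idx_all[(traj.atoms["monomer_id"].to_numpy()[idx_all] == m)]
        order = np.lexsort(
            (
                traj.atoms["atom_name"].to_numpy()[sub],
                traj.atoms["residue_number"].to_numpy()[sub],
            )
        )
        sub = sub[order]
        per_mono.append(sub)
        keys.append(
            list(
                zip(
                    traj.atoms["residue_number"].to_numpy()[sub],
                    traj.atoms["atom_name"].to_numpy()[sub],
                )
            )
        )
    if not (keys[0] == keys[1] == keys[2]):
        raise ValueError("monomers have mismatching residue/atom sequences")
    atoms = traj.atoms.iloc[per_mono[0]].reset_index(drop=True).copy()
    atoms["monomer_id"] = "A"
    coords = np.concatenate([traj.coords[:, sub, :] for sub in per_mono], axis=0)
    provenance = pd.DataFrame(
        {
            "monomer": np.repeat(labels, traj.n_frames),
            "source_frame": np.tile(np.arange(traj.n_frames), 3),
        }
    )
    return EnsembleTrajectory(coords, atoms), provenance


def cutoff_for_coverage(
    matrix: np.ndarray,
    target_coverage: float,
    max_clusters: int,
    grid_step: float = 0.1,
    grid_max: float | None = None,
) -> tuple[float, ClusterResult]:
    """Smallest grid cutoff whose top-``max_clusters`` coverage meets target.

    Scans cutoffs ``grid_step, 2*grid_step, ...`` up to the matrix maximum
    (or ``grid_max``) and returns the first that reaches the target; raises
    with the best achievable coverage if none does.
    """
    if not 0.0 < target_coverage <= 1.0:
        raise ValueError("target_coverage must be in (0, 1]")
    if max_clusters < 1:
        raise ValueError("max_clusters must be >= 1")
    mat = np.asarray(matrix, dtype=float)
    top = grid_max if grid_max is not None else float(mat.max()) + grid_step
    grid = np.arange(grid_step, top + grid_step / 2, grid_step)
    best_cov = 0.0
    best_cut = grid[0]
    for cutoff in grid:
        result = daura_cluster(mat, float(cutoff))
        cov = result.coverage(max_clusters)
        if cov >= target_coverage:
            return float(cutoff), result
        if cov > best_cov:
            best_cov, best_cut = cov, float(cutoff)
    raise ValueError(
        f"coverage target {target_coverage:.2f} within {max_clusters} clusters "
        f"unreachable on grid (best {best_cov:.2f} at {best_cut:.2f} A)"
    )
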