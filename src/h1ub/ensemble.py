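"""Ensemble analysis: pooling runs, RMSD clustering, precision, densities.

Saved models from independent sampling runs are pooled, the best-scoring
subset (500 by default) is clustered on the RMSD of the mobile proteins
computed in the shared frame (the reference protein is fixed during
sampling, so no superposition is applied), cluster centers are the members
with minimum mean RMSD to the other members, per-protein precision is the
RMSF about the center, and per-cluster/per-protein localization densities
are voxelized occupancy maps written as MRC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .sampler import SavedModels

__all__ = [
    "ClusteringConfig",
    "ClusterResult",
    "LocalizationDensity",
    "ThresholdClustering",
    "pool_and_select",
    "rmsd_matrix",
    "threshold_cluster",
    "precision",
    "localization_density",
    "convergence_report",
]


@dataclass(frozen=True)
class ClusteringConfig:
    """Ensemble-clustering parameters.

    Production defaults: the 500 best-scoring pooled models, 10 Å RMSD
    cutoff, RMSD computed over the mobile proteins with the fixed protein
    as alignment reference.
    """

    n_best: int = 500
    rmsd_cutoff: float = 10.0
    mobile: tuple[str, ...] = ()
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.rmsd_cutoff <= 0:
            raise ValueError("cutoff must be > 0")


@dataclass
class ClusterResult:
    """Cluster memberships, centers, sizes and per-protein precision."""

    labels: np.ndarray
    centers: list[int]
    sizes: list[int]
    precision: dict[int, dict[str, float]] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


class ThresholdClustering(ClusterMixin, BaseEstimator):
    """Greedy leader clustering on a precomputed distance matrix.

    Repeatedly seeds a cluster with the unassigned model having the most
    unassigned neighbors within ``cutoff`` (ties broken by lowest index) and
    assigns those neighbors to it; the center is then recomputed as the
    member minimizing mean distance to the other members. Deterministic
    given the matrix.

    Attributes set by :meth:`fit`: ``labels_`` (cluster id per model, sorted
    by decreasing cluster size) and ``centers_`` (model index per cluster).
    """

    def __init__(self, cutoff: float = 10.0):
        self.cutoff = cutoff

    def fit(self, X: np.ndarray, y=None) -> "ThresholdClustering":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValueError("X must be a square distance matrix")
        if not np.allclose(X, X.T, atol=1e-8):
            raise ValueError("X must be symmetric")
        n = X.shape[0]
        within = X <= self.cutoff
        unassigned = np.ones(n, dtype=bool)
        labels = np.full(n, -1, dtype=int)
        centers: list[int] = []
        cluster = 0
        while unassigned.any():
            counts = (within & unassigned[None, :]).sum(axis=1)
            counts[~unassigned] = -1
            seed = int(np.argmax(counts))
            members = np.nonzero(within[seed] & unassigned)[0]
            labels[members] = cluster
            unassigned[members] = False
            sub = X[np.ix_(members, members)]
            center = int(members[np.argmin(sub.mean(axis=1))])
            centers.append(center)
            cluster += 1
        # relabel by decreasing size, stable
        sizes = np.bincount(labels)
        order = np.argsort(-sizes, kind="stable")
        remap = np.empty_like(order)
        remap[order] = np.arange(len(order))
        self.labels_ = remap[labels]
        self.centers_ = [centers[i] for i in order]
        self.sizes_ = [int(sizes[i]) for i in order]
        return self

    def fit_predict(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).labels_


def pool_and_select(runs: Sequence[SavedModels], n_best: int = 500) -> SavedModels:
    """Pool runs and keep the ``n_best`` lowest-score models (stable tie-break).

    The tie-break and output ordering are by (score, run, replica, frame),
    which makes the selection invariant to the order the runs are supplied.
    """
    pooled = SavedModels.concatenate(list(runs))
    if len(pooled) < n_best:
        warnings.warn(
            f"only {len(pooled)} models available, fewer than n_best={n_best}; taking all",
            stacklevel=2,
        )
        n_best = len(pooled)
    ordered = pooled.sorted_by_score()
    return SavedModels(
        ordered.coords[:n_best].copy(), ordered.scores[:n_best].copy(),
        ordered.replica[:n_best].copy(), ordered.frame[:n_best].copy(),
        ordered.run[:n_best].copy(),
    )


def _mobile_index(system, mobile: Sequence[str]) -> np.ndarray:
    idx = np.nonzero(np.isin(system.proteins, list(mobile)))[0]
    if idx.size == 0:
        raise ValueError(f"mobile selection {mobile} matches no beads")
    return idx


def rmsd_matrix(
    models: SavedModels, system, mobile: Sequence[str]
) -> np.ndarray:
    """Pairwise RMSD (Å) over the mobile beads, computed in the shared frame.

    No superposition is applied: the reference protein is fixed during
    sampling, so all models already share its frame. Requires identical
    bead ordering across models.
    """
    idx = _mobile_index(system, mobile)
    coords = np.asarray(models.coords, dtype=float)[:, idx, :]
    n = coords.shape[0]
    # ||a-b||^2 summed over beads via the Gram-matrix identity
    flat = coords.reshape(n, -1)
    sq = np.sum(flat**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * flat @ flat.T
    np.maximum(d2, 0.0, out=d2)
    rmsd = np.sqrt(d2 / idx.size)
    np.fill_diagonal(rmsd, 0.0)
    return 0.5 * (rmsd + rmsd.T)


def threshold_cluster(rmsd: np.ndarray, cutoff: float = 10.0) -> ClusterResult:
    """Leader clustering of a model ensemble at the given RMSD cutoff."""
    est = ThresholdClustering(cutoff=cutoff).fit(rmsd)
    return ClusterResult(labels=est.labels_, centers=est.centers_, sizes=est.sizes_)


def precision(
    result: ClusterResult, models: SavedModels, system, cluster: int = 0
) -> dict[str, float]:
    """Per-protein RMSF (Å) of cluster members about the cluster center."""
    members = np.nonzero(result.labels == cluster)[0]
    if members.size == 0:
        raise ValueError(f"cluster {cluster} has no members")
    center = np.asarray(models.coords[result.centers[cluster]], dtype=float)
    out: dict[str, float] = {}
    for prot in np.unique(system.proteins):
        idx = system.protein_beads(str(prot))
        dev = np.asarray(models.coords, dtype=float)[members][:, idx, :] - center[idx]
        out[str(prot)] = float(np.sqrt(np.mean(np.sum(dev**2, axis=-1))))
    return out


@dataclass
class LocalizationDensity:
    """Voxelized occupancy of one protein across cluster members.

    ``grid[ix, iy, iz]`` is the fraction of members whose bead spheres
    intersect the voxel centered at ``origin + (ix+.5, iy+.5, iz+.5) * spacing``.
    """

    origin: np.ndarray
    spacing: float
    grid: np.ndarray

    def total_mass(self) -> float:
        return float(self.grid.sum())

    def write_mrc(self, path) -> None:
        import mrcfile

        with mrcfile.new(str(path), overwrite=True) as mrc:
            # MRC axis order is z, y, x
            mrc.set_data(np.ascontiguousarray(self.grid.T).astype(np.float32))
            mrc.voxel_size = self.spacing
            mrc.header.origin.x = self.origin[0]
            mrc.header.origin.y = self.origin[1]
            mrc.header.origin.z = self.origin[2]

    @staticmethod
    def read_mrc(path) -> "LocalizationDensity":
        import mrcfile

        with mrcfile.open(str(path)) as mrc:
            grid = np.asarray(mrc.data, dtype=float).T.copy()
            spacing = float(mrc.voxel_size.x)
            origin = np.array(
                [mrc.header.origin.x, mrc.header.origin.y, mrc.header.origin.z],
                dtype=float,
            )
        return LocalizationDensity(origin=origin, spacing=spacing, grid=grid)


def localization_density(
    result: ClusterResult,
    models: SavedModels,
    system,
    protein: str,
    cluster: int = 0,
    spacing: float = 5.0,
) -> LocalizationDensity:
    """Voxel occupancy map of one protein within one cluster.

    A voxel counts a member if any of the member's bead spheres of that
    protein comes within the bead radius of the voxel center; counts are
    normalized by the member count.
    """
    if spacing <= 0:
        raise ValueError("voxel spacing must be > 0")
    members = np.nonzero(result.labels == cluster)[0]
    idx = system.protein_beads(protein)
    if idx.size == 0:
        raise ValueError(f"unknown protein {protein!r}")
    coords = np.asarray(models.coords, dtype=float)[members][:, idx, :]
    radii = system.radii[idx]
    pad = float(np.max(radii)) + spacing
    lo = coords.reshape(-1, 3).min(axis=0) - pad
    hi = coords.reshape(-1, 3).max(axis=0) + pad
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    if np.any(shape <= 0):
        raise ValueError("degenerate zero-extent grid")
    grid = np.zeros(shape, dtype=float)
    centers = [lo[k] + (np.arange(shape[k]) + 0.5) * spacing for k in range(3)]
    gx, gy, gz = np.meshgrid(*centers, indexing="ij")
    voxel_xyz = np.stack([gx, gy, gz], axis=-1)
    for m in range(coords.shape[0]):
        hit = np.zeros(tuple(shape), dtype=bool)
        for b in range(idx.size):
            d2 = np.sum((voxel_xyz - coords[m, b]) ** 2, axis=-1)
            hit |= d2 <= radii[b] ** 2
        grid += hit
    grid /= max(coords.shape[0], 1)
    return LocalizationDensity(origin=lo, spacing=spacing, grid=grid)


def convergence_report(
    per_run: Sequence[np.ndarray], pooled: np.ndarray
) -> pd.DataFrame:
    """Best-overlap matching between each run's clusters and pooled clusters.

    ``per_run[r]`` and ``pooled`` are label arrays over the same model set
    (models absent from a run marked -1). For each run cluster the pooled
    cluster with the largest overlap (Jaccard) is reported.
    """
    if len(per_run) < 2:
        raise ValueError("need at least two runs for a convergence report")
    rows = []
    pooled = np.asarray(pooled)
    for r, labels in enumerate(per_run):
        labels = np.asarray(labels)
        for c in np.unique(labels[labels >= 0]):
            mask = labels == c
            best_overlap, best_pool = 0.0, -1
            for p in np.unique(pooled[pooled >= 0]):
                pmask = pooled == p
                inter = np.sum(mask & pmask)
                union = np.sum(mask | pmask)
                j = inter / union if union else 0.0
                if j > best_overlap:
                    best_overlap, best_pool = j, int(p)
            rows.append(
                {
                    "run": r,
                    "run_cluster": int(c),
                    "pooled_cluster": best_pool,
                    "overlap": best_overlap,
                    "size": int(mask.sum()),
                }
            )
    return pd.DataFrame(rows, columns=["run", "run_cluster", "pooled_cluster", "overlap", "size"])
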