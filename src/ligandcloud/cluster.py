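"""Conformational clustering and ligand-cloud summarisation.

Backbone-RMSD clustering in the GROMOS (Daura) scheme: compute all
pairwise superposed RMSDs, then repeatedly take the conformation with the
most neighbours within a cutoff (default 2.0 A), make it and its
neighbours a cluster with the central conformation as representative, and
remove them.  Cluster populations are fractions of *all* frames, so a
dominant, well-populated top-8 (e.g. a cumulative 77% versus 50%) reads
directly as a tighter ensemble.

The "ligand cloud" of a cluster is the scatter of ligand centres of mass
of its member frames after superposing each member's peptide onto the
representative -- a compact picture of where the ligand sits around that
conformational basin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Trajectory
from .errors import ConfigurationError, DegenerateGeometryError

__all__ = [
    "SuperpositionResult",
    "ClusterSet",
    "LigandCloud",
    "kabsch_superpose",
    "pairwise_rmsd_matrix",
    "daura_cluster",
    "ligand_cloud",
    "cluster_population_report",
    "default_rmsd_subset",
]

_BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper rotation/translation and the resulting RMSD (A).

    The transform maps mobile coordinates onto the reference frame:
    ``y = (x - mobile_center) @ rotation.T + reference_center``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    mobile_center: np.ndarray
    reference_center: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted transform to arbitrary coordinates."""
        return (coords - self.mobile_center) @ self.rotation.T + self.reference_center


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    subset: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch, via SVD).

    The rotation is always proper (determinant +1): a reflection is never
    used even when it would fit a mirror image better.  The RMSD is over
    the fitted subset after superposition.

    Raises
    ------
    DegenerateGeometryError
        If the subset has fewer than 3 atoms or is (nearly) collinear.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if subset is None:
        subset = np.arange(len(mobile))
    subset = np.asarray(subset, dtype=int)
    if subset.size < 3:
        raise DegenerateGeometryError("superposition subset needs >= 3 atoms")
    x = mobile[subset]
    y = reference[subset]
    cx = x.mean(axis=0)
    cy = y.mean(axis=0)
    x0 = x - cx
    y0 = y - cy
    s = np.linalg.svd(x0, compute_uv=False)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise DegenerateGeometryError("superposition subset is collinear")
    cov = x0.T @ y0
    u, sig, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    msd = (np.sum(x0 ** 2) + np.sum(y0 ** 2) - 2.0 * (sig[0] + sig[1] + d * sig[2])) / len(subset)
    rmsd = float(np.sqrt(max(msd, 0.0)))
    return SuperpositionResult(rot, cy - rot @ cx, rmsd, cx, cy)


def default_rmsd_subset(traj: Trajectory) -> np.ndarray:
    """Backbone atoms (N/CA/C/O) if present, else all peptide particles."""
    bb = traj.atom_indices_by_name(_BACKBONE_NAMES)
    # a coarse-grained chain exposes only CA beads; both cases are covered
    return bb if bb.size >= 3 else traj.peptide_indices


def pairwise_rmsd_matrix(
    traj: Trajectory, subset: np.ndarray | None = None
) -> np.ndarray:
    """Symmetric matrix of superposed RMSDs (A) between all frame pairs.

    Batched Kabsch: for each frame the covariances against every other
    frame are built in one einsum and decomposed with a stacked SVD, so a
    thousand-frame trajectory stays in the seconds range.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if subset is None:
        subset = default_rmsd_subset(traj)
    subset = np.asarray(subset, dtype=int)
    if subset.size < 3:
        raise DegenerateGeometryError("RMSD subset needs >= 3 atoms")

    x = traj.coords()[:, subset, :]
    x = x - x.mean(axis=1, keepdims=True)
    g = np.einsum("fak,fak->f", x, x)
    m = subset.size
    n = traj.n_frames
    out = np.zeros((n, n))
    for i in range(n - 1):
        rest = x[i + 1:]
        cov = np.einsum("ak,nal->nkl", x[i], rest)
        u, sig, vt = np.linalg.svd(cov)
        det = np.linalg.det(u) * np.linalg.det(vt)
        corr = np.where(det < 0, -1.0, 1.0)
        tr = sig[:, 0] + sig[:, 1] + corr * sig[:, 2]
        msd = (g[i] + g[i + 1:] - 2.0 * tr) / m
        out[i, i + 1:] = np.sqrt(np.maximum(msd, 0.0))
    return out + out.T


@dataclass
class ClusterSet:
    """Frame assignments, populations, and representatives.

    Clusters are ordered by decreasing size (the greedy scheme produces
    non-increasing sizes by construction); populations are fractions of
    all frames and sum to one.
    """

    assignment: np.ndarray      # frame -> cluster id (0-based)
    populations: np.ndarray     # fraction per cluster
    representatives: np.ndarray  # frame index per cluster

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        self.populations = np.asarray(self.populations, dtype=float)
        self.representatives = np.asarray(self.representatives, dtype=int)
        if not np.isclose(self.populations.sum(), 1.0, atol=1e-9):
            raise ValueError("populations must sum to 1")
        if np.any(np.diff(self.populations) > 1e-12):
            raise ValueError("clusters must be ordered by decreasing population")

    @property
    def n_clusters(self) -> int:
        return len(self.populations)

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cluster)

    def to_frame(self) -> pd.DataFrame:
        sizes = np.bincount(self.assignment, minlength=self.n_clusters)
        return pd.DataFrame({
            "cluster": np.arange(self.n_clusters),
            "size": sizes,
            "population_pct": 100.0 * self.populations,
            "representative_frame": self.representatives,
        })


def daura_cluster(rmsd: np.ndarray, cutoff: float = 2.0) -> ClusterSet:
    """Greedy neighbour-count (GROMOS-style) clustering of an RMSD matrix.

    Iteratively the unassigned frame with the most unassigned neighbours
    within ``cutoff`` (ties broken by lowest frame index) becomes a
    representative; it and its neighbours form a cluster and are removed.
    Removed frames never re-enter, so populations are fractions of all
    frames.
    """
    rmsd = np.asarray(rmsd, dtype=float)
    if rmsd.size == 0:
        raise ValueError("empty RMSD matrix")
    if rmsd.ndim != 2 or rmsd.shape[0] != rmsd.shape[1]:
        raise ValueError("RMSD matrix must be square")
    n = rmsd.shape[0]
    adj = rmsd <= cutoff
    np.fill_diagonal(adj, True)

    remaining = np.ones(n, dtype=bool)
    assignment = np.full(n, -1, dtype=int)
    reps: list[int] = []
    sizes: list[int] = []
    cid = 0
    while remaining.any():
        counts = adj[:, remaining].sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(adj[center] & remaining)
        assignment[members] = cid
        remaining[members] = False
        reps.append(center)
        sizes.append(len(members))
        cid += 1
    populations = np.array(sizes, dtype=float) / n
    return ClusterSet(assignment, populations, np.array(reps))


@dataclass
class LigandCloud:
    """Per-cluster ligand centres of mass in the representative's frame."""

    points: dict[int, np.ndarray]   # cluster id -> (cluster size, 3)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid, pts in self.points.items():
            for p in pts:
                rows.append((cid, p[0], p[1], p[2]))
        return pd.DataFrame(rows, columns=["cluster", "x", "y", "z"])


def ligand_cloud(
    traj: Trajectory,
    clusters: ClusterSet,
    subset: np.ndarray | None = None,
) -> LigandCloud:
    """Ligand centre-of-mass scatter for each cluster.

    Every member frame's peptide is superposed onto its cluster
    representative (over ``subset``, default the backbone/bead subset used
    for clustering) and the same rigid transform carries the ligand; the
    mass-weighted ligand centre of mass is one cloud point.
    """
    if not traj.has_ligand:
        raise ConfigurationError("trajectory has no ligand atoms")
    if subset is None:
        subset = default_rmsd_subset(traj)
    lig = traj.ligand_indices
    masses = traj.masses()[lig]
    coords = traj.coords()
    points: dict[int, np.ndarray] = {}
    for cid in range(clusters.n_clusters):
        rep = clusters.representatives[cid]
        pts = []
        for f in clusters.members(cid):
            sup = kabsch_superpose(coords[f], coords[rep], subset)
            lig_xyz = sup.apply(coords[f][lig])
            com = (masses[:, None] * lig_xyz).sum(axis=0) / masses.sum()
            pts.append(com)
        points[cid] = np.array(pts)
    return LigandCloud(points)


def cluster_population_report(
    clusters: ClusterSet | Sequence[float],
    top_k: int = 8,
) -> tuple[pd.DataFrame, int]:
    """Top-k cluster populations (1 decimal, %) and their rounded sum.

    Accepts a :class:`ClusterSet` or a bare population sequence (fractions
    summing to ~1, or percentages).  The cumulative percentage is rounded
    half-up to the nearest integer, the convention behind statements like
    "a total of about 77% occupancy compared to 50%".
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if isinstance(clusters, ClusterSet):
        pops = 100.0 * clusters.populations
    else:
        pops = np.asarray(list(clusters), dtype=float)
        if pops.sum() <= 1.0 + 1e-6:
            pops = 100.0 * pops
    pops = np.sort(pops)[::-1]
    top = pops[: min(top_k, len(pops))]
    table = pd.DataFrame({
        "rank": np.arange(1, len(top) + 1),
        "population_pct": np.round(top, 1),
    })
    cumulative = int(np.floor(top.sum() + 0.5))
    return table, cumulative
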