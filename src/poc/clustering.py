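"""Conformer clustering by heavy-atom RMSD after optimal superposition.

Frames are compared by least-squares rigid superposition (Kabsch algorithm,
proper rotations only), clustered hierarchically on the resulting RMSD
matrix, and each cluster is summarized by its medoid — the member with the
smallest mean RMSD to the rest of the cluster, ties broken by lowest frame
index so output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .ensemble import Ensemble, Frame

__all__ = [
    "RmsdMatrix",
    "Clustering",
    "DegenerateGeometryError",
    "kabsch_superpose",
    "pairwise_rmsd",
    "cluster_frames",
]


class DegenerateGeometryError(ValueError):
    """Too few or collinear atoms for a well-conditioned superposition."""


@dataclass(frozen=True)
class RmsdMatrix:
    values: np.ndarray                 # (n, n), Å, symmetric, zero diagonal
    atom_subset: tuple[int, ...]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9) or np.any(np.diag(v) != 0) or np.any(v < 0):
            raise ValueError("RMSD matrix must be symmetric, non-negative, zero-diagonal")


@dataclass(frozen=True)
class Clustering:
    labels: np.ndarray                 # frame -> cluster id (0-based)
    representatives: dict[int, int]    # cluster id -> medoid frame index
    linkage_method: str
    parameter: float | int

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def _check_subset(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegenerateGeometryError("superposition needs at least 3 atoms")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateGeometryError("atom subset is collinear")


def kabsch_superpose(
    frame_a: Frame | np.ndarray,
    frame_b: Frame | np.ndarray,
    atom_subset: Sequence[int] | None = None,
) -> float:
    """Minimum RMSD (Å) between two frames under rigid superposition.

    Rotation + translation only; reflections are excluded by the usual
    determinant sign correction on the SVD of the covariance matrix.
    """
    a = frame_a.coords if isinstance(frame_a, Frame) else np.asarray(frame_a, dtype=float)
    b = frame_b.coords if isinstance(frame_b, Frame) else np.asarray(frame_b, dtype=float)
    if atom_subset is not None:
        idx = list(atom_subset)
        a, b = a[idx], b[idx]
    if a.shape != b.shape:
        raise ValueError("frames must expose the same atom subset")
    _check_subset(a)
    _check_subset(b)

    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    # proper rotation: flip the smallest singular direction if det < 0
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    resid = ac @ rot.T - bc
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def pairwise_rmsd(
    ensemble: Ensemble,
    heavy_atoms_only: bool = True,
    atom_subset: Sequence[int] | None = None,
) -> RmsdMatrix:
    """All-pairs superposed RMSD; each pair computed once, symmetric by
    construction.  Heavy-atom selection drops every atom whose element is H.
    """
    if ensemble.n_frames < 2:
        raise ValueError("pairwise RMSD needs at least 2 frames")
    if atom_subset is None:
        idx = list(range(ensemble.n_atoms))
    else:
        idx = list(atom_subset)
    if heavy_atoms_only:
        elements = ensemble.elements
        idx = [i for i in idx if elements[i].upper() != "H"]
    xyz = ensemble.coords[:, idx]
    n = ensemble.n_frames
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = kabsch_superpose(xyz[i], xyz[j])
            values[i, j] = values[j, i] = r
    return RmsdMatrix(values=values, atom_subset=tuple(idx))


def _medoid(values: np.ndarray, members: np.ndarray) -> int:
    sub = values[np.ix_(members, members)]
    mean_rmsd = sub.mean(axis=1)
    # ties broken by lowest frame index: argmin returns the first minimum
    return int(members[int(np.argmin(mean_rmsd))])


def cluster_frames(
    matrix: RmsdMatrix,
    method: Literal["average", "single", "complete"] = "average",
    k: int | None = None,
    threshold: float | None = None,
) -> Clustering:
    """Agglomerative clustering of frames on the RMSD matrix.

    Cut the dendrogram either into exactly ``k`` clusters or at an RMSD
    ``threshold`` (exactly one of the two must be given).  Representatives
    are cluster medoids.
    """
    if (k is None) == (threshold is None):
        raise ValueError("specify exactly one of k or threshold")
    n = matrix.n
    if k is not None and not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    z = linkage(squareform(matrix.values, checks=False), method=method)
    if k is not None:
        raw = fcluster(z, t=k, criterion="maxclust")
        parameter: float | int = k
    else:
        raw = fcluster(z, t=threshold, criterion="distance")
        parameter = threshold
    # relabel 0-based in order of first appearance for stable output
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, c in enumerate(raw):
        labels[i] = remap.setdefault(int(c), len(remap))
    representatives = {
        cid: _medoid(matrix.values, np.flatnonzero(labels == cid))
        for cid in range(len(remap))
    }
    return Clustering(
        labels=labels,
        representatives=representatives,
        linkage_method=method,
        parameter=parameter,
    )
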