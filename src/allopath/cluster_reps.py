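"""Superposition, pairwise RMSD, k-means clustering and representatives.

An ensemble is partitioned into conformational classes by (i) computing the
best-fit RMSD between every pair of frames over a stated atom selection,
(ii) embedding the RMSD matrix into a Euclidean space by classical
multidimensional scaling, (iii) running k-means there, and (iv) reporting
each cluster's medoid — the member frame with the smallest summed RMSD to
its cluster — as the representative conformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .structure_io import Ensemble

__all__ = ["Clustering", "kabsch_superpose", "pairwise_rmsd", "kmeans_frames",
           "mds_embedding", "DegenerateFitError"]


class DegenerateFitError(ValueError):
    """Too few or collinear atoms for a least-squares superposition."""


@dataclass
class Clustering:
    """K-means partition of an ensemble with medoid representatives."""

    labels: np.ndarray          # frame -> cluster id, shape (n_frames,)
    k: int
    populations: np.ndarray     # per-cluster fraction, sums to 1
    medoids: np.ndarray         # per-cluster representative frame index
    inertia: float              # within-cluster sum of squares in the embedding
    seed: int
    n_init: int

    def __post_init__(self) -> None:
        assert abs(self.populations.sum() - 1.0) < 1e-9
        for c, m in enumerate(self.medoids):
            assert self.labels[m] == c


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     atom_sel: np.ndarray | None = None,
                     ) -> tuple[np.ndarray, float]:
    """Least-squares superpose ``mobile`` onto ``reference``.

    The optimal proper rotation (determinant +1, reflections excluded) and
    translation are fitted on ``atom_sel`` only and applied to *all* mobile
    atoms.  Returns ``(transformed, rmsd)`` where the RMSD is over the fit
    selection after superposition.

    Raises
    ------
    DegenerateFitError
        If the selection has fewer than 3 atoms or is collinear.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    sel = np.arange(len(mobile)) if atom_sel is None else np.asarray(atom_sel, int)
    if len(sel) < 3:
        raise DegenerateFitError("superposition needs at least 3 fit atoms")
    x = mobile[sel]
    y = reference[sel]
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    # collinearity: rank of the centered coordinates < 2
    if np.linalg.matrix_rank(x0, tol=1e-8) < 2 or np.linalg.matrix_rank(y0, tol=1e-8) < 2:
        raise DegenerateFitError("fit atoms are collinear")
    h = x0.T @ y0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.diag([1.0, 1.0, d])
    rot = u @ diag @ vt
    transformed = (mobile - xc) @ rot + yc
    delta = transformed[sel] - y
    rmsd = float(np.sqrt((delta ** 2).sum() / len(sel)))
    return transformed, rmsd


def rmsd_nofit(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without superposition."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.sqrt(((a - b) ** 2).sum() / len(a)))


def pairwise_rmsd(ensemble: Ensemble, atom_sel: np.ndarray) -> np.ndarray:
    """All-against-all best-fit RMSD over an atom selection.

    Each entry is computed once per unordered pair, so the matrix is
    symmetric by construction with an exactly zero diagonal.
    """
    if ensemble.n_frames < 2:
        raise ValueError("pairwise RMSD needs at least 2 frames")
    sel = np.asarray(atom_sel, int)
    n = ensemble.n_frames
    out = np.zeros((n, n))
    # precenter the selections once; RMSD needs only the selected atoms
    xs = ensemble.coords[:, sel, :]
    xs = xs - xs.mean(axis=1, keepdims=True)
    if sel.size < 3:
        raise DegenerateFitError("pairwise RMSD needs at least 3 fit atoms")
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _fit_rmsd_centered(xs[i], xs[j])
    return out


def _fit_rmsd_centered(x0: np.ndarray, y0: np.ndarray) -> float:
    """Best-fit RMSD of two pre-centered coordinate sets (Kabsch via SVD)."""
    h = x0.T @ y0
    u, s, vt = np.linalg.svd(h)
    if np.linalg.det(u @ vt) < 0:
        s = s.copy()
        s[-1] = -s[-1]
    e0 = (x0 ** 2).sum() + (y0 ** 2).sum()
    msd = max((e0 - 2.0 * s.sum()) / len(x0), 0.0)
    return float(np.sqrt(msd))


def mds_embedding(rmsd: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """Classical (Torgerson) MDS embedding of a distance matrix.

    Only components with positive eigenvalues are kept, up to
    ``min(n_frames - 1, 10)`` by default.
    """
    d2 = np.asarray(rmsd, float) ** 2
    n = d2.shape[0]
    if n_components is None:
        n_components = min(n - 1, 10)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:n_components]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > max(1e-12, 1e-9 * abs(evals[0]) if evals.size else 0)
    if not keep.any():
        return np.zeros((n, 1))
    return evecs[:, keep] * np.sqrt(evals[keep])


def kmeans_frames(rmsd: np.ndarray, k: int, seed: int = 0,
                  n_init: int = 10) -> Clustering:
    """K-means on the MDS embedding of an RMSD matrix, with medoids.

    The best of ``n_init`` seeded restarts (by within-cluster sum of squares)
    is kept.  The representative of each cluster is its medoid: the member
    frame minimizing the summed RMSD to all members, ties broken toward the
    lowest frame index.
    """
    rmsd = np.asarray(rmsd, float)
    n = rmsd.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, n_frames={n}], got {k}")
    if n_init < 1:
        raise ValueError("n_init must be ≥ 1")

    emb = mds_embedding(rmsd)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(emb)

    populations = np.bincount(labels, minlength=k) / n
    if (populations == 0).any():
        raise RuntimeError(
            f"empty cluster after {n_init} k-means restarts; reduce k")

    medoids = np.empty(k, dtype=int)
    for c in range(k):
        members = np.flatnonzero(labels == c)
        total = rmsd[np.ix_(members, members)].sum(axis=1)
        medoids[c] = members[int(np.argmin(total))]  # argmin returns first tie

    return Clustering(labels=labels, k=k, populations=populations,
                      medoids=medoids, inertia=float(km.inertia_),
                      seed=seed, n_init=n_init)
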