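"""Interpretation of reweighted ensembles.

Pairwise Calpha RMSD, weight-aware density-based clustering (DBSCAN where a
frame's contribution to the core-point count is its reweighted statistical
weight scaled by the ensemble size), silhouette-based neighborhood-radius
selection, weighted RMSD distributions and state-population summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import DBSCAN
from sklearn.metrics import silhouette_samples

from .errors import InputError

__all__ = [
    "ClusterResult",
    "pairwise_rmsd",
    "rmsd_matrix",
    "weighted_dbscan",
    "select_radius",
    "weighted_rmsd_distribution",
    "excess_population",
    "cluster_representatives",
]


def _kabsch_rotation(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix aligning centered ``mobile`` onto centered
    ``ref`` (least-squares, proper rotation)."""
    h = mobile.T @ ref
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    fix = np.diag([1.0, 1.0, d])
    return u @ fix @ vt


def pairwise_rmsd(
    coords_a: np.ndarray, coords_b: np.ndarray, superpose: bool = True
) -> float:
    """RMSD between two traces, optionally after optimal superposition."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise InputError("coordinate sets must share shape (n_atoms, 3)")
    if a.shape[0] < 3:
        raise InputError("need at least 3 atoms")
    if superpose:
        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)
        a = a @ _kabsch_rotation(a, b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_matrix(frames, superpose: str | None = "first") -> np.ndarray:
    """Pairwise RMSD matrix over frames (Angstrom).

    ``superpose="first"`` (default) aligns every frame once onto frame 0 and
    then uses plain pairwise RMSD — O(F) Kabsch fits instead of O(F^2);
    ``"pairwise"`` runs a Kabsch fit per pair; ``None`` uses raw coordinates.
    """
    coords = np.asarray(getattr(frames, "coords", frames), dtype=float)
    if coords.ndim != 3:
        raise InputError("frames must have shape (n_frames, n_atoms, 3)")
    F, A, _ = coords.shape
    if superpose == "pairwise":
        out = np.zeros((F, F))
        for i in range(F):
            for j in range(i + 1, F):
                out[i, j] = out[j, i] = pairwise_rmsd(coords[i], coords[j])
        return out
    if superpose == "first":
        ref = coords[0] - coords[0].mean(axis=0)
        aligned = np.empty_like(coords)
        for i in range(F):
            x = coords[i] - coords[i].mean(axis=0)
            aligned[i] = x @ _kabsch_rotation(x, ref)
        coords = aligned
    elif superpose is not None:
        raise InputError("superpose must be 'first', 'pairwise' or None")
    flat = coords.reshape(F, A * 3)
    return squareform(pdist(flat) / np.sqrt(A))


def _check_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InputError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8) or not np.allclose(np.diag(d), 0.0):
        raise InputError("distance matrix must be symmetric with zero diagonal")
    return d


@dataclass
class ClusterResult:
    """Weighted DBSCAN outcome: labels (-1 = outlier) and populations (%)."""

    labels: np.ndarray
    populations: dict          # cluster id -> % of total weight
    outlier_population: float  # % of total weight
    radius: float
    min_population_fraction: float

    @property
    def n_clusters(self) -> int:
        return len(self.populations)


def weighted_dbscan(
    distance_matrix,
    weights,
    radius: float,
    min_population_fraction: float = 0.1,
) -> ClusterResult:
    """DBSCAN on a precomputed RMSD matrix with reweighted frame weights.

    A frame is a core point iff the summed weight of its neighborhood
    (scaled by the ensemble size N, i.e. ``sum Omega_k * N``) reaches
    ``min_population_fraction * N``; with uniform weights this reduces to
    standard DBSCAN with ``min_samples = min_population_fraction * N``.
    """
    d = _check_distance_matrix(distance_matrix)
    w = np.asarray(getattr(weights, "values", weights), dtype=float)
    n = d.shape[0]
    if w.shape != (n,):
        raise InputError("weights length must match the distance matrix")
    if abs(w.sum() - 1.0) > 1e-8:
        raise InputError("weights must be normalized")
    # sklearn wants an integer min_samples; rescale so the core condition
    # sum(Omega * N) >= fraction * N becomes sum(Omega * M / fraction) >= M
    M = 1_000_000
    db = DBSCAN(eps=radius, min_samples=M, metric="precomputed")
    labels = db.fit(d, sample_weight=w * (M / min_population_fraction)).labels_
    populations = {
        int(c): float(w[labels == c].sum()) * 100.0
        for c in sorted(set(labels))
        if c != -1
    }
    outlier = float(w[labels == -1].sum()) * 100.0
    return ClusterResult(
        labels=labels,
        populations=populations,
        outlier_population=outlier,
        radius=float(radius),
        min_population_fraction=float(min_population_fraction),
    )


def select_radius(
    distance_matrix,
    weights,
    radii,
    min_population_fraction: float = 0.1,
) -> tuple[float, dict]:
    """Scan neighborhood radii; return the one maximizing the weighted mean
    silhouette over clustered frames (ties -> smaller radius), plus the
    per-radius scores (NaN where fewer than 2 clusters formed)."""
    radii = np.asarray(radii, dtype=float)
    if radii.size < 2:
        raise InputError("need at least 2 radii")
    d = _check_distance_matrix(distance_matrix)
    w = np.asarray(getattr(weights, "values", weights), dtype=float)
    scores: dict[float, float] = {}
    best = None
    for r in radii:
        res = weighted_dbscan(d, w, r, min_population_fraction)
        clustered = res.labels >= 0
        if res.n_clusters < 2 or np.count_nonzero(clustered) < 3:
            scores[float(r)] = float("nan")
            continue
        sil = silhouette_samples(
            d[np.ix_(clustered, clustered)],
            res.labels[clustered],
            metric="precomputed",
        )
        wc = w[clustered]
        score = float(np.sum(sil * wc) / wc.sum())
        scores[float(r)] = score
        if best is None or score > best[1] + 1e-12:
            best = (float(r), score)
    if best is None:
        raise InputError("no radius produced at least 2 clusters")
    return best[0], scores


def weighted_rmsd_distribution(
    rmsd_to_reference, weights, bins
) -> tuple[np.ndarray, np.ndarray]:
    """Weight-summed histogram of per-frame RMSD values, normalized to unit
    area; returns (density, bin_edges)."""
    r = np.asarray(rmsd_to_reference, dtype=float)
    w = np.asarray(getattr(weights, "values", weights), dtype=float)
    if r.size == 0:
        raise InputError("empty RMSD input")
    if r.shape != w.shape:
        raise InputError("rmsd and weights lengths differ")
    hist, edges = np.histogram(r, bins=bins, weights=w, density=True)
    return hist, edges


def excess_population(weights, labels, label_a: str, label_b: str) -> float:
    """Population difference ``P(label_a) - P(label_b)`` under the given
    weights; every frame must carry one of the two labels."""
    w = np.asarray(getattr(weights, "values", weights), dtype=float)
    labels = np.asarray(labels, dtype=object)
    if w.shape != labels.shape:
        raise InputError("weights and labels lengths differ")
    unknown = set(labels) - {label_a, label_b}
    if unknown:
        raise InputError(f"unknown labels: {sorted(map(str, unknown))}")
    return float(w[labels == label_a].sum() - w[labels == label_b].sum())


def cluster_representatives(result: ClusterResult, weights) -> dict:
    """Highest-weight frame index per cluster."""
    w = np.asarray(getattr(weights, "values", weights), dtype=float)
    reps = {}
    for c in result.populations:
        members = np.nonzero(result.labels == c)[0]
        reps[c] = int(members[np.argmax(w[members])])
    return reps
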