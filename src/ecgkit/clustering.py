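"""Density-based beat grouping and outlier rejection.

The clustering stage groups morphologically similar beats by density
reachability (DBSCM), retains within each group only the beats that stay
concentrated around the group's medoid (CBCR: threshold mean + k*std of
medoid distances, capped by the maximum distance), and finally prunes
beats whose normalized cross-correlation against their group's medoid
waveform falls below a threshold.  PCA is available to project the
feature space before clustering.

The density clustering is implemented here directly (it is the method
under study, and determinism of the border-point tie-break matters):
points with >= min_pts neighbours within eps are core; clusters are the
maximal density-reachable sets, grown breadth-first in index order so
border points join the first core cluster that reaches them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ClusterResult",
    "DistanceStats",
    "distance_matrix",
    "standardize",
    "dbscm",
    "auto_eps",
    "cbcr_filter",
    "ncc",
    "ncc_prune",
    "pca_project",
]

NOISE = -1


@dataclass
class DistanceStats:
    """Mean, standard deviation and maximum of member-to-medoid distances."""

    mean: float
    std: float
    max: float
    medoid: int  # row index of the cluster medoid in the full matrix


@dataclass
class ClusterResult:
    """Per-beat integer labels (-1 = noise), core flags and per-cluster stats."""

    labels: np.ndarray
    core_flags: np.ndarray
    stats: dict[int, DistanceStats] = field(default_factory=dict)
    eps: float = 0.0
    min_pts: int = 0

    def cluster_ids(self) -> list[int]:
        return sorted(c for c in set(self.labels.tolist()) if c != NOISE)


def distance_matrix(F: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Pairwise distances; symmetric with a zero diagonal."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    D = cdist(F, F, metric=metric)
    np.fill_diagonal(D, 0.0)
    return 0.5 * (D + D.T)


def standardize(F: np.ndarray) -> np.ndarray:
    """Per-column zero mean / unit variance; constant columns are left
    centred only (mixed-unit features would otherwise dominate distances)."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    mu = F.mean(axis=0)
    sd = F.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (F - mu) / sd


def auto_eps(F: np.ndarray, k: int = 4) -> float:
    """4-NN distance elbow heuristic: the knee of the sorted k-th
    neighbour distance curve (point of maximum deviation from the chord)."""
    D = distance_matrix(F)
    n = D.shape[0]
    if n <= k:
        return float(np.median(D)) if n > 1 else 1.0
    kdist = np.sort(np.sort(D, axis=1)[:, k])
    x = np.linspace(0.0, 1.0, n)
    chord = kdist[0] + x * (kdist[-1] - kdist[0])
    knee = int(np.argmax(kdist - chord)) if np.any(kdist - chord > 0) else int(np.argmax(chord - kdist))
    eps = float(kdist[knee])
    return eps if eps > 0 else float(max(kdist[-1], 1e-12))


def dbscm(F: np.ndarray, eps: float, min_pts: int = 5,
          precomputed: np.ndarray | None = None) -> ClusterResult:
    """Density-based spatial clustering of the beat feature points.

    A point is core when >= ``min_pts`` points (itself included) lie
    within ``eps``.  Clusters are grown breadth-first from unvisited core
    points in row order; non-reachable points are labelled -1 (sparse
    regions = noise).  Deterministic and invariant to row permutation up
    to label renaming.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    D = distance_matrix(F) if precomputed is None else np.asarray(precomputed, dtype=float)
    n = D.shape[0]
    neighbors = [np.flatnonzero(D[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, NOISE, dtype=int)
    cluster = 0
    for i in range(n):
        if labels[i] != NOISE or not core[i]:
            continue
        # breadth-first expansion of the density-reachable set
        labels[i] = cluster
        queue = [i]
        while queue:
            p = queue.pop(0)
            if not core[p]:
                continue
            for q in neighbors[p]:
                if labels[q] == NOISE:
                    labels[q] = cluster
                    queue.append(q)
        cluster += 1

    stats: dict[int, DistanceStats] = {}
    for c in range(cluster):
        members = np.flatnonzero(labels == c)
        sub = D[np.ix_(members, members)]
        medoid_local = int(np.argmin(sub.sum(axis=1)))
        d_to_medoid = sub[medoid_local]
        stats[c] = DistanceStats(
            mean=float(d_to_medoid.mean()),
            std=float(d_to_medoid.std()),
            max=float(d_to_medoid.max()),
            medoid=int(members[medoid_local]),
        )
    return ClusterResult(labels=labels, core_flags=core, stats=stats,
                         eps=float(eps), min_pts=int(min_pts))


def cbcr_filter(F: np.ndarray, result: ClusterResult,
                k_max: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Concentration-based cluster retention.

    Within each cluster, beats farther from the medoid than
    min(mean + k_max*std, max) are discarded; all noise-labelled beats are
    discarded.  Returns (retained indices, discarded indices) — a disjoint,
    exhaustive partition of all beats.  The medoid itself is never
    discarded.
    """
    n = len(result.labels)
    if not result.stats:
        warnings.warn("empty clustering: every beat discarded", stacklevel=2)
        return np.array([], dtype=int), np.arange(n)
    D = distance_matrix(F)
    retained: list[int] = []
    discarded: list[int] = []
    for i in range(n):
        c = result.labels[i]
        if c == NOISE:
            discarded.append(i)
            continue
        st = result.stats[c]
        threshold = min(st.mean + k_max * st.std, st.max)
        if i != st.medoid and D[i, st.medoid] > threshold:
            discarded.append(i)
        else:
            retained.append(i)
    return np.array(retained, dtype=int), np.array(discarded, dtype=int)


def ncc(a: np.ndarray, b: np.ndarray, max_lag: int | None = None) -> tuple[float, int]:
    """Normalized cross-correlation, searched over lags.

    Both windows are mean-removed and scaled by their norms, so values lie
    in [-1, 1].  Returns the signed value at the lag of largest |NCC| and
    that lag.  Zero-variance input yields NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("windows must have equal length")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan"), 0
    c = np.correlate(a, b, mode="full") / (na * nb)
    lags = np.arange(-len(a) + 1, len(a))
    if max_lag is not None:
        keep = np.abs(lags) <= max_lag
        c, lags = c[keep], lags[keep]
    k = int(np.argmax(np.abs(c)))
    return float(c[k]), int(lags[k])


def ncc_prune(windows: np.ndarray, labels: np.ndarray,
              references: dict[int, np.ndarray], threshold: float = 0.8,
              max_lag: int | None = None) -> np.ndarray:
    """Retain beats whose NCC against their cluster's reference waveform
    reaches ``threshold``.  Beats with undefined NCC (flat windows) are
    pruned with a warning; noise-labelled beats are pruned."""
    retained: list[int] = []
    for i, (w, c) in enumerate(zip(windows, labels)):
        if c == NOISE or c not in references:
            continue
        value, _ = ncc(w, references[c], max_lag=max_lag)
        if np.isnan(value):
            warnings.warn(f"beat {i}: zero-variance window, NCC undefined; pruned",
                          stacklevel=2)
            continue
        if value >= threshold:
            retained.append(i)
    return np.array(retained, dtype=int)


def pca_project(F: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project onto the top-k principal axes of the mean-centred data.

    Returns (projected n x k matrix, components k x p with orthonormal
    rows, explained variances).  Variances equal the top covariance
    eigenvalues (population convention) in non-increasing order; directions
    beyond the data rank get zero variance (with a warning).
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    n, p = F.shape
    if k > p:
        raise ValueError("k cannot exceed the number of features")
    X = F - F.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s ** 2 / n
    if k > np.sum(s > 1e-12 * (s[0] if s.size else 1.0)):
        warnings.warn("k exceeds data rank; trailing variances are zero", stacklevel=2)
    comps = Vt[:k]
    if comps.shape[0] < k:  # rank-deficient thin SVD: pad with orthonormal complement
        pad = np.zeros((k - comps.shape[0], p))
        comps = np.vstack([comps, pad])
        var = np.concatenate([var, np.zeros(k - len(var))])
    # deterministic sign convention: largest-magnitude entry positive
    for row in comps:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1
    return X @ comps.T, comps, var[:k]
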