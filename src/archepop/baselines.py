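"""Binary-restricted variants of Archetypal Analysis and matching utilities.

Restricting the ancestry fractions alpha to one-hot rows (and relaxing the
convex-hull constraint on centers) turns the AA alternation into Lloyd's
K-Means; restricting *both* alpha and beta to one-hot turns it into
alternating-descent K-Medoids on squared Euclidean cost.  AA is the smooth
relaxation of the latter.  These reductions are provided as reference
points, together with a Hungarian column matcher for comparing soft
assignment matrices against a truth Q or another method's output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = ["HardClustering", "kmeans_binary_alpha", "kmedoids_binary", "match_columns"]


@dataclass
class HardClustering:
    """Hard partition: per-sample labels in [0, K), K x D centers, total cost."""

    labels: np.ndarray
    centers: np.ndarray
    inertia: float
    empty_clusters: list[int]

    @property
    def K(self) -> int:
        return self.centers.shape[0]


def _init_rows(data: np.ndarray, K: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.choice(data.shape[0], size=K, replace=False)


def kmeans_binary_alpha(
    data: np.ndarray,
    K: int,
    seed: int = 0,
    init_centers: np.ndarray | None = None,
    max_iter: int = 100,
) -> HardClustering:
    """Lloyd's K-Means: AA with one-hot alpha and unconstrained centers.

    Alternates nearest-center assignment and mean updates until the
    partition is stable.  ``init_centers`` (K x D) overrides the seeded
    random-row initialization, e.g. to share an init with a reference
    implementation.  Clusters that end up empty keep their previous
    center and are reported in ``empty_clusters``.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if not 1 <= K <= n:
        raise ValueError(f"K must be in [1, {n}], got {K}")
    centers = (
        np.asarray(init_centers, dtype=float).copy()
        if init_centers is not None
        else data[_init_rows(data, K, seed)].copy()
    )
    labels = np.full(n, -1)
    for _ in range(max_iter):
        d2 = cdist(data, centers, metric="sqeuclidean")
        new_labels = d2.argmin(axis=1)
        if (new_labels == labels).all():
            break
        labels = new_labels
        for j in range(K):
            members = labels == j
            if members.any():
                centers[j] = data[members].mean(axis=0)
    d2 = cdist(data, centers, metric="sqeuclidean")
    inertia = float(d2[np.arange(n), labels].sum())
    empty = [j for j in range(K) if not (labels == j).any()]
    return HardClustering(labels=labels, centers=centers, inertia=inertia, empty_clusters=empty)


def kmedoids_binary(
    data: np.ndarray, K: int, seed: int = 0, max_iter: int = 100, restarts: int = 10
) -> HardClustering:
    """Alternating-descent K-Medoids: AA with one-hot alpha *and* beta.

    Centers are data rows.  Alternates nearest-medoid assignment with a
    within-cluster medoid update minimizing the squared Euclidean cost;
    ties break toward the lower index.  An emptied cluster is re-seeded
    to the point farthest from its current medoid assignment.  The
    descent only finds a local optimum, so ``restarts`` independent
    seeded initializations are run and the cheapest solution returned.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if not 1 <= K <= n:
        raise ValueError(f"K must be in [1, {n}], got {K}")
    d2_all = cdist(data, data, metric="sqeuclidean")
    best: HardClustering | None = None
    for r in range(restarts):
        if r == 0:
            init = _build_init(d2_all, K)  # deterministic greedy BUILD start
        else:
            rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(r,)))
            init = np.sort(rng.choice(n, size=K, replace=False))
        cand = _kmedoids_once(data, d2_all, K, init, max_iter)
        if best is None or cand.inertia < best.inertia:
            best = cand
    assert best is not None
    return best


def _build_init(d2_all: np.ndarray, K: int) -> np.ndarray:
    """Greedy BUILD initialization: each pick maximizes the cost reduction."""
    n = d2_all.shape[0]
    medoids = [int(d2_all.sum(axis=0).argmin())]
    nearest = d2_all[:, medoids[0]].copy()
    while len(medoids) < K:
        gains = np.maximum(nearest[:, None] - d2_all, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        c = int(gains.argmax())
        medoids.append(c)
        nearest = np.minimum(nearest, d2_all[:, c])
    return np.asarray(medoids, dtype=int)


def _kmedoids_once(
    data: np.ndarray, d2_all: np.ndarray, K: int, init: np.ndarray, max_iter: int
) -> HardClustering:
    n = data.shape[0]
    medoids = init.copy()
    labels = np.full(n, -1)
    for _ in range(max_iter):
        d2 = d2_all[:, medoids]
        new_labels = d2.argmin(axis=1)
        # re-seed empty clusters to the worst-assigned point
        for j in range(K):
            if not (new_labels == j).any():
                worst = int(d2[np.arange(n), new_labels].argmax())
                medoids[j] = worst
                new_labels = d2_all[:, medoids].argmin(axis=1)
        new_medoids = medoids.copy()
        for j in range(K):
            members = np.flatnonzero(new_labels == j)
            if members.size == 0:  # duplicate medoids can leave a cluster empty
                continue
            costs = d2_all[np.ix_(members, members)].sum(axis=0)
            new_medoids[j] = members[int(costs.argmin())]  # argmin ties -> lower index
        if (new_labels == labels).all() and (new_medoids == medoids).all():
            break
        labels, medoids = new_labels, new_medoids
    # swap refinement: alternating (Voronoi) descent alone can stall in
    # local optima that a single medoid<->point exchange escapes; run
    # best-improvement swaps to convergence (skipped for large panels
    # where the quadratic scan would dominate)
    if n <= 512:
        cost = float(d2_all[:, medoids].min(axis=1).sum())
        improved = True
        while improved:
            improved = False
            for j in range(K):
                for c in range(n):
                    if c in medoids:
                        continue
                    trial = medoids.copy()
                    trial[j] = c
                    trial_cost = float(d2_all[:, trial].min(axis=1).sum())
                    if trial_cost < cost - 1e-12:
                        medoids, cost, improved = trial, trial_cost, True
    d2 = d2_all[:, medoids]
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(n), labels].sum())
    empty = [j for j in range(K) if not (labels == j).any()]
    return HardClustering(labels=labels, centers=data[medoids].copy(), inertia=inertia, empty_clusters=empty)


def match_columns(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal column matching of two N x K matrices by Pearson correlation.

    Returns ``(perm, mean_r)`` where ``perm[j]`` is the column of ``b``
    matched to column j of ``a``, chosen by Hungarian assignment to
    maximize the summed per-pair correlations, and ``mean_r`` is the mean
    matched correlation.  Zero-variance columns correlate as 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    k = a.shape[1]
    corr = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            sa, sb = a[:, i].std(), b[:, j].std()
            if sa == 0 or sb == 0:
                continue
            corr[i, j] = np.corrcoef(a[:, i], b[:, j])[0, 1]
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(k, dtype=int)
    perm[rows] = cols
    return perm, float(corr[rows, cols].mean())
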