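"""Similarity network fusion: self-tuning affinity kernels, cross-network
diffusion, spectral clustering and cluster-number heuristics.

Given one sample-similarity network per omics view, fusion iteratively
updates each view's status matrix with the average of the other views,
propagated through the view's own K-nearest-neighbour kernel:

    P_v  <-  S_v · mean_{u != v}(P_u) · S_vᵀ,

followed by renormalization and symmetrization.  After T iterations the
per-view status matrices are averaged into one fused network.  Strong edges
supported by any view diffuse into the others, so the fused network can
recover structure no single view resolves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .containers import AlignmentError

EPS = 1e-12


@dataclass
class SNFConfig:
    """Fusion hyperparameters: K nearest neighbours, kernel width multiplier
    sigma, and T diffusion iterations."""

    K: int = 20
    sigma: float = 0.5
    T: int = 20
    k_range: tuple[int, ...] = tuple(range(2, 11))
    seed: int = 0

    def validate(self, n_samples: int | None = None) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if n_samples is not None and self.K >= n_samples:
            raise ValueError(f"K={self.K} must be < n_samples={n_samples}")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if any(k < 2 for k in self.k_range):
            raise ValueError("k_range entries must be >= 2")


@dataclass
class AffinityGraph:
    """An n x n nonnegative sample-similarity (or distance) matrix."""

    matrix: np.ndarray
    sample_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix must be n x n matching sample_ids")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def pairwise_distance(values: np.ndarray, sample_ids: list[str]) -> AffinityGraph:
    """Squared Euclidean distances between sample rows."""
    x = np.asarray(values, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if np.isnan(x).any():
        raise ValueError("NaN in feature matrix; filter features first")
    sq = (x * x).sum(axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.maximum(d, 0.0, out=d)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return AffinityGraph(d, list(sample_ids), normalized=False)


def affinity_matrix(d: AffinityGraph, cfg: SNFConfig) -> AffinityGraph:
    """Self-tuning Gaussian kernel on squared distances.

    W(i,j) = exp(-d(i,j) / (sigma * eps_ij)) with the local scale
    eps_ij = (mean of i's K nearest distances + mean of j's + d(i,j)) / 3.
    """
    cfg.validate(n_samples=d.n)
    dist = d.matrix
    n = d.n
    # mean distance to the K nearest neighbours, self excluded
    sorted_d = np.sort(dist, axis=1)[:, 1 : cfg.K + 1]
    mu = sorted_d.mean(axis=1)
    eps = (mu[:, None] + mu[None, :] + dist) / 3.0
    if np.any(eps <= 0):
        warnings.warn(
            "degenerate local scale (duplicate-heavy input); flooring eps",
            RuntimeWarning,
            stacklevel=2,
        )
        eps = np.maximum(eps, EPS)
    w = np.exp(-dist / (cfg.sigma * eps))
    w = (w + w.T) / 2.0
    return AffinityGraph(w, d.sample_ids, normalized=False)


def _normalize_status(w: np.ndarray) -> np.ndarray:
    """Full-kernel normalization: off-diagonal rows sum to 1/2, diagonal 1/2."""
    off = w.copy()
    np.fill_diagonal(off, 0.0)
    rowsum = off.sum(axis=1)
    rowsum[rowsum == 0] = EPS
    p = off / (2.0 * rowsum[:, None])
    np.fill_diagonal(p, 0.5)
    return p


def _knn_kernel(w: np.ndarray, K: int) -> np.ndarray:
    """Sparse local kernel: each row keeps its K nearest neighbours
    (largest affinities, self excluded) renormalized to sum 1."""
    n = w.shape[0]
    s = np.zeros_like(w)
    off = w.copy()
    np.fill_diagonal(off, -np.inf)
    nn = np.argsort(-off, axis=1)[:, :K]
    rows = np.repeat(np.arange(n), K)
    s[rows, nn.ravel()] = w[rows, nn.ravel()]
    rowsum = s.sum(axis=1)
    rowsum[rowsum == 0] = EPS
    return s / rowsum[:, None]


def fuse_networks(ws: list[AffinityGraph], cfg: SNFConfig) -> AffinityGraph:
    """Run T cross-diffusion iterations and return the fused network."""
    if len(ws) < 2:
        raise ValueError("need at least two views to fuse")
    ids0 = ws[0].sample_ids
    for g in ws[1:]:
        if g.sample_ids != ids0:
            raise AlignmentError("views carry different sample IDs or order")
    cfg.validate(n_samples=len(ids0))
    m = len(ws)
    ps = [_normalize_status(g.matrix) for g in ws]
    ss = [_knn_kernel(g.matrix, cfg.K) for g in ws]
    for _ in range(cfg.T):
        new_ps = []
        for v in range(m):
            others = sum(ps[u] for u in range(m) if u != v) / (m - 1)
            p = ss[v] @ others @ ss[v].T
            p = _normalize_status(p)
            p = (p + p.T) / 2.0
            new_ps.append(p)
        ps = new_ps
    fused = sum(ps) / m
    fused = (fused + fused.T) / 2.0
    return AffinityGraph(fused, ids0, normalized=True)


def _spectral_embedding(w: np.ndarray, k: int) -> np.ndarray:
    """Top-k eigenvectors of the symmetric-normalized affinity, row-normalized."""
    deg = w.sum(axis=1)
    deg[deg == 0] = EPS
    d_isqrt = 1.0 / np.sqrt(deg)
    a = d_isqrt[:, None] * w * d_isqrt[None, :]
    a = (a + a.T) / 2.0
    n = a.shape[0]
    _, vecs = eigh(a, subset_by_index=(n - k, n - 1))
    u = vecs[:, ::-1]
    norms = np.linalg.norm(u, axis=1)
    norms[norms == 0] = EPS
    return u / norms[:, None]


def spectral_cluster(g: AffinityGraph, k: int, seed: int = 0) -> np.ndarray:
    """Normalized spectral clustering; labels in {1..k}, deterministic per seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    w = (g.matrix + g.matrix.T) / 2.0
    n_components = _count_components(w)
    if n_components > k:
        warnings.warn(
            f"graph has {n_components} connected components > k={k}",
            RuntimeWarning,
            stacklevel=2,
        )
    emb = _spectral_embedding(w, k)
    km = KMeans(n_clusters=k, n_init=20, random_state=seed)
    return km.fit_predict(emb) + 1


def _count_components(w: np.ndarray) -> int:
    from scipy.sparse.csgraph import connected_components

    ncomp, _ = connected_components((w > EPS).astype(int), directed=False)
    return int(ncomp)


def _laplacian_eigenvalues(w: np.ndarray) -> np.ndarray:
    deg = w.sum(axis=1)
    deg[deg == 0] = EPS
    d_isqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(w.shape[0]) - d_isqrt[:, None] * w * d_isqrt[None, :]
    lap = (lap + lap.T) / 2.0
    return np.sort(np.linalg.eigvalsh(lap))


def _discretisation(u: np.ndarray, max_iter: int = 30) -> tuple[np.ndarray, float]:
    """Iterative SVD rotation aligning continuous eigenvectors with a
    one-hot cluster indicator; returns the indicator and the alignment cost."""
    n, k = u.shape
    # greedy init: pick k maximally orthogonal rows as rotation anchors
    r = np.zeros((k, k))
    r[:, 0] = u[n // 2]
    c = np.zeros(n)
    for j in range(1, k):
        c += np.abs(u @ r[:, j - 1])
        r[:, j] = u[int(np.argmin(c))]
    last_obj = 0.0
    x = None
    for _ in range(max_iter):
        m = u @ r
        x = np.zeros_like(m)
        x[np.arange(n), np.argmax(m, axis=1)] = 1.0
        uu, svals, vt = np.linalg.svd(x.T @ u)
        obj = float(svals.sum())
        if abs(obj - last_obj) < 1e-10:
            break
        last_obj = obj
        r = (uu @ vt).T
    cost = float(np.linalg.norm(u @ r - x) ** 2)
    return x, cost


def estimate_num_clusters(g: AffinityGraph, cfg: SNFConfig) -> tuple[int, int]:
    """Estimate the cluster number by the eigen-gap of the normalized
    Laplacian (primary) and by the rotation-cost heuristic (secondary)."""
    w = (g.matrix + g.matrix.T) / 2.0
    n = w.shape[0]
    k_range = [k for k in cfg.k_range if 2 <= k <= n - 1]
    if not k_range:
        raise ValueError("k_range contains no feasible candidate")
    evals = _laplacian_eigenvalues(w)
    gaps = {k: evals[k] - evals[k - 1] for k in k_range}
    best_gap = max(gaps.values())
    if best_gap < 1e-10:
        warnings.warn(
            "degenerate affinity: no eigen-gap structure in k_range",
            RuntimeWarning,
            stacklevel=2,
        )
        return min(k_range), min(k_range)
    k_eigengap = min(k for k, v in gaps.items() if v == best_gap)
    costs = {}
    for k in k_range:
        emb = _spectral_embedding(w, k)
        _, cost = _discretisation(emb)
        costs[k] = cost / np.sqrt(k)  # mild scale correction across k
    best_cost = min(costs.values())
    k_rotation = min(k for k, v in costs.items() if v == best_cost)
    return k_eigengap, k_rotation
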