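"""Similarity network fusion: per-platform affinity networks and cross-diffusion.

Each platform's samples are embedded as a patient similarity network via a
scaled exponential kernel on Euclidean distances; the networks are then
fused by iterative cross-diffusion, in which each view's global transition
matrix is propagated through the other views' sparse K-nearest-neighbor
kernels. The fused network is what gets clustered into molecular subtypes.

State machine of :class:`AffinityNetwork`:
``raw`` (kernel) -> ``global_normalized`` (full transition matrix P) and
``local_kernel`` (sparse KNN transition matrix S); ``fuse`` consumes
(P, S) pairs and emits a ``fused`` network.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import DataError, ExpressionMatrix, check_aligned

logger = logging.getLogger("oligosnf")

#: default kernel / fusion parameters (recommended ranges of the SNF method)
DEFAULT_K = 20
DEFAULT_MU = 0.5
DEFAULT_T = 20


@dataclasses.dataclass
class AffinityNetwork:
    """Samples x samples nonnegative similarity / transition matrix."""

    matrix: np.ndarray
    sample_ids: list[str]
    state: str  # raw | global_normalized | local_kernel | fused
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise DataError("affinity matrix shape does not match sample_ids")

    @property
    def n(self) -> int:
        return len(self.sample_ids)


def _effective_k(K: int, n: int) -> int:
    """Neighbor count bounded away from degenerate values (cap at n/3, min 1)."""
    return max(1, min(K, n - 1, n // 3 if n >= 6 else n - 1))


def pairwise_distance(expr: ExpressionMatrix, standardize: bool = True) -> np.ndarray:
    """Euclidean sample-sample distances, optionally on per-feature z-scores.

    Zero-variance features are dropped with a warning when standardizing
    (their z-score is undefined; they carry no between-sample signal).
    """
    if expr.n_samples < 3:
        raise DataError("pairwise_distance needs at least 3 samples")
    X = expr.values
    if standardize:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=0, keepdims=True)
        zero = sd.ravel() == 0
        if zero.any():
            warnings.warn(
                f"dropping {int(zero.sum())} zero-variance features before z-scoring",
                stacklevel=2,
            )
            X, mu, sd = X[~zero], mu[~zero], sd[~zero]
        X = (X - mu) / sd
    D = squareform(pdist(X.T, metric="euclidean"))
    return D


def affinity_kernel(
    D: np.ndarray,
    sample_ids: list[str],
    K: int = DEFAULT_K,
    mu: float = DEFAULT_MU,
) -> AffinityNetwork:
    """Scaled exponential similarity kernel.

    ``W[i,j] = exp(-d2(i,j) / (mu * eps(i,j)))`` on squared distances
    ``d2 = d^2``, with the local scale
    ``eps(i,j) = (mean_K(i) + mean_K(j) + d2(i,j)) / 3``, where ``mean_K(i)``
    is the mean squared distance from i to its K nearest neighbors. Working
    throughout in squared distances makes W exactly invariant to uniform
    rescaling of all distances. Duplicate points (eps = 0) are handled by
    flooring eps at machine tolerance so resampling procedures never
    hard-fail.
    """
    D = np.asarray(D, float)
    n = D.shape[0]
    if not (0.3 <= mu <= 0.8):
        raise ValueError(f"mu must lie in [0.3, 0.8], got {mu}")
    if K >= n:
        raise ValueError(f"K={K} must be smaller than n={n}")
    k = _effective_k(K, n)
    D2 = D ** 2
    # mean squared distance to K nearest neighbors, self excluded
    Dsort = np.sort(D2 + np.diag(np.full(n, np.inf)), axis=1)
    mean_k = Dsort[:, :k].mean(axis=1)
    eps = (mean_k[:, None] + mean_k[None, :] + D2) / 3.0
    floor = np.finfo(float).eps
    if (eps <= 0).any():
        warnings.warn("duplicate samples: flooring kernel scale at machine tolerance",
                      stacklevel=2)
        eps = np.maximum(eps, floor)
    W = np.exp(-D2 / (mu * eps))
    W = (W + W.T) / 2.0
    return AffinityNetwork(W, list(sample_ids), "raw", {"K": K, "mu": mu})


def global_normalize(net: AffinityNetwork) -> AffinityNetwork:
    """Full transition matrix: P(i,j) = W(i,j) / (2 * sum_{k!=i} W(i,k)), diag 1/2.

    Every row sums to 1; the half-mass diagonal keeps the iteration
    numerically stable. Only ``raw`` networks are accepted: normalized and
    fused networks are already transition matrices, and re-normalizing one
    is always a caller bug (the map is a fixed point on its own output, so
    a silent second pass would hide the state error rather than corrupt
    values).
    """
    if net.state != "raw":
        raise DataError(f"global_normalize expects a raw network, got {net.state!r}")
    W = net.matrix.copy()
    np.fill_diagonal(W, 0.0)
    rowsum = W.sum(axis=1)
    if (rowsum <= 0).any():
        bad = net.sample_ids[int(np.argmax(rowsum <= 0))]
        raise DataError(f"isolated sample {bad!r}: all off-diagonal affinities zero")
    P = W / (2.0 * rowsum[:, None])
    np.fill_diagonal(P, 0.5)
    return AffinityNetwork(P, list(net.sample_ids), "global_normalized", dict(net.params))


def local_kernel(net: AffinityNetwork, K: int | None = None) -> AffinityNetwork:
    """Sparse KNN transition matrix: row-normalized over each sample's K
    nearest neighbors (by affinity, self excluded), zero elsewhere.

    Ties at the K-th neighbor are broken by sample order, so the operation
    is deterministic.
    """
    W = net.matrix
    n = W.shape[0]
    if K is None:
        K = int(net.params.get("K", DEFAULT_K))
    if K >= n:
        raise ValueError(f"K={K} must be smaller than n={n}")
    S = np.zeros_like(W)
    idx = np.arange(n)
    for i in range(n):
        cand = idx[idx != i]
        # sort by affinity descending, ties by sample index ascending
        order = cand[np.lexsort((cand, -W[i, cand]))]
        nbrs = order[:K]
        total = W[i, nbrs].sum()
        if total <= 0:
            raise DataError(f"sample {net.sample_ids[i]!r} has zero affinity to all neighbors")
        S[i, nbrs] = W[i, nbrs] / total
    return AffinityNetwork(S, list(net.sample_ids), "local_kernel",
                           {**net.params, "K": K})


def build_view(
    expr: ExpressionMatrix,
    K: int = DEFAULT_K,
    mu: float = DEFAULT_MU,
    standardize: bool = True,
) -> tuple[AffinityNetwork, AffinityNetwork]:
    """Distance -> kernel -> (global transition P, sparse KNN kernel S) for one platform."""
    D = pairwise_distance(expr, standardize=standardize)
    W = affinity_kernel(D, expr.sample_ids, K=K, mu=mu)
    return global_normalize(W), local_kernel(W)


def _renormalize(P: np.ndarray) -> np.ndarray:
    """Re-apply global normalization to an updated transition matrix."""
    Q = P.copy()
    np.fill_diagonal(Q, 0.0)
    rowsum = Q.sum(axis=1)
    rowsum[rowsum == 0] = 1.0
    Q = Q / (2.0 * rowsum[:, None])
    np.fill_diagonal(Q, 0.5)
    return Q


def fuse(
    networks: list[tuple[AffinityNetwork, AffinityNetwork]],
    T: int = DEFAULT_T,
) -> AffinityNetwork:
    """Cross-diffusion of m >= 2 views into one fused network.

    Iterates ``P_v <- S_v @ mean(P_u, u != v) @ S_v.T`` for T rounds,
    re-normalizing each view after every round, then averages the views,
    symmetrizes and globally normalizes. With a single view the global
    transition matrix is returned unchanged (logged).
    """
    if not networks:
        raise ValueError("fuse requires at least one view")
    check_aligned(*[p.sample_ids for p, _ in networks],
                  *[s.sample_ids for _, s in networks])
    for P, S in networks:
        if P.state != "global_normalized" or S.state != "local_kernel":
            raise DataError("fuse expects (global_normalized, local_kernel) pairs")
    sample_ids = list(networks[0][0].sample_ids)
    if len(networks) == 1:
        logger.info("fuse called with a single view; returning it unchanged")
        out = networks[0][0]
        return AffinityNetwork(out.matrix.copy(), sample_ids, "fused", dict(out.params))

    Ps = [P.matrix.copy() for P, _ in networks]
    Ss = [S.matrix for _, S in networks]
    m = len(Ps)
    for t in range(T):
        new = []
        for v in range(m):
            others = sum(Ps[u] for u in range(m) if u != v) / (m - 1)
            new.append(Ss[v] @ others @ Ss[v].T)
        Ps = [_renormalize(P) for P in new]
        for v, P in enumerate(Ps):
            if not np.isfinite(P).all():
                raise DataError(f"non-finite values in view {v} at fusion iteration {t + 1}")
    fused = sum(Ps) / m
    fused = (fused + fused.T) / 2.0
    fused = _renormalize(fused)
    params = {**networks[0][0].params, "T": T, "views": m}
    return AffinityNetwork(fused, sample_ids, "fused", params)


def fuse_expression(
    views: list[ExpressionMatrix],
    K: int = DEFAULT_K,
    mu: float = DEFAULT_MU,
    T: int = DEFAULT_T,
    standardize: bool = True,
) -> AffinityNetwork:
    """Convenience: build per-view networks from expression and fuse them."""
    check_aligned(*[v.sample_ids for v in views])
    return fuse([build_view(v, K=K, mu=mu, standardize=standardize) for v in views], T=T)
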