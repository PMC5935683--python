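"""Spectral clustering of the fused network, cluster-number estimation and
consensus stability assessment.

The fused patient network is partitioned by normalized-Laplacian spectral
clustering (top-k eigenvectors, row-normalized, k-means with multi-restart).
The number of clusters is ranked by the eigengap heuristic; consensus
clustering over subsampled re-runs quantifies the stability of the
partition. The pipeline fixes k = 3 by default — the number of molecular
subtypes the analysis is designed around — but the eigengap diagnostics are
always reported.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components

from .io import DataError
from .snf import AffinityNetwork, global_normalize

DEFAULT_KMEANS_RESTARTS = 50


def _kmeans_restarts(X: np.ndarray, k: int, n_restarts: int, seed: int) -> np.ndarray:
    """Multi-restart Lloyd k-means, all restarts advanced in lockstep.

    The permutation test re-runs spectral clustering hundreds of times on
    embeddings of at most a few hundred points in k dimensions, so the
    restarts are vectorized across a (restarts, n, k) tensor instead of
    dispatching to a general-purpose implementation. k-means++ seeding,
    best-inertia restart returned.
    """
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    R = n_restarts
    centers = np.empty((R, k, X.shape[1]))
    # k-means++ init per restart
    first = rng.integers(0, n, size=R)
    centers[:, 0] = X[first]
    closest = np.sum((X[None, :, :] - centers[:, 0][:, None, :]) ** 2, axis=2)  # R x n
    for j in range(1, k):
        total = closest.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        cum = np.cumsum(closest / total, axis=1)
        draw = rng.random((R, 1))
        pick = (cum < draw).sum(axis=1).clip(max=n - 1)
        centers[:, j] = X[pick]
        d_new = np.sum((X[None, :, :] - centers[:, j][:, None, :]) ** 2, axis=2)
        closest = np.minimum(closest, d_new)

    assign = np.zeros((R, n), dtype=np.int64)
    for _ in range(100):
        # R x n x k squared distances
        d = np.sum((X[None, :, None, :] - centers[:, None, :, :]) ** 2, axis=3)
        new_assign = d.argmin(axis=2)
        if (new_assign == assign).all():
            break
        assign = new_assign
        for j in range(k):
            mask = assign == j  # R x n
            cnt = mask.sum(axis=1)
            ok = cnt > 0
            sums = mask.astype(float) @ X  # R x dim
            centers[ok, j] = sums[ok] / cnt[ok, None]
            # empty cluster: reseed at the point farthest from its center
            if (~ok).any():
                far = d.min(axis=2).argmax(axis=1)
                centers[~ok, j] = X[far[~ok]]
    d = np.sum((X[None, :, None, :] - centers[:, None, :, :]) ** 2, axis=3)
    inertia = d.min(axis=2).sum(axis=1)
    return d[int(inertia.argmin())].argmin(axis=1)


@dataclasses.dataclass
class SubtypeResult:
    """Per-sample subtype labels plus cluster-number diagnostics."""

    labels: np.ndarray           # integers 1..k
    k: int
    sample_ids: list[str]
    eigenvalues: np.ndarray      # leading normalized-Laplacian spectrum (ascending)
    eigengap_scores: dict[int, float] | None = None
    consensus_matrix: np.ndarray | None = None

    def label_of(self, sample_id: str) -> int:
        return int(self.labels[self.sample_ids.index(sample_id)])


def _symmetric_affinity(net: AffinityNetwork) -> np.ndarray:
    A = np.asarray(net.matrix, float)
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 0.0)
    return A


def _laplacian_spectrum(A: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Smallest-m eigenpairs of the symmetric normalized Laplacian of A."""
    deg = A.sum(axis=1)
    if (deg <= 0).any():
        raise DataError("affinity matrix has an isolated sample")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(A.shape[0]) - d_inv_sqrt[:, None] * A * d_inv_sqrt[None, :]
    L = (L + L.T) / 2.0
    vals, vecs = eigh(L, subset_by_index=(0, min(m, A.shape[0]) - 1))
    return vals, vecs


def canonical_relabel(raw_labels: np.ndarray) -> np.ndarray:
    """Renumber clusters 1..k by order of first appearance (lowest member index)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw_labels)
    nxt = 1
    for i, lab in enumerate(raw_labels):
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out[i] = mapping[raw_labels[i]]
    return out


def spectral_cluster(
    fused: AffinityNetwork,
    k: int,
    seed: int = 0,
    n_restarts: int = DEFAULT_KMEANS_RESTARTS,
) -> SubtypeResult:
    """Normalized-Laplacian spectral clustering of a fused network.

    Embeds samples into the top-k Laplacian eigenvectors, row-normalizes the
    embedding and runs k-means with ``n_restarts`` seeded restarts. Labels
    are renumbered canonically (cluster 1 contains the lowest-index sample).
    A network with more connected components than k is rejected.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    A = _symmetric_affinity(fused)
    n = A.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    n_comp, _ = connected_components((A > 1e-12).astype(int), directed=False)
    if n_comp > k:
        raise DataError(f"network has {n_comp} connected components but k={k}")

    n_eig = min(max(k + 1, 2), n)
    vals, vecs = _laplacian_spectrum(A, n_eig)
    U = vecs[:, :k]
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = U / norms
    if k == n:
        raw = np.arange(n)
    else:
        raw = _kmeans_restarts(U, k, n_restarts, int(seed) % (2**31))
        if len(np.unique(raw)) < k:  # extremely degenerate embedding
            raise DataError("k-means produced an empty cluster")
    labels = canonical_relabel(raw)
    return SubtypeResult(labels=labels, k=k, sample_ids=list(fused.sample_ids),
                         eigenvalues=vals)


def estimate_k(
    fused: AffinityNetwork, k_min: int = 2, k_max: int = 8
) -> tuple[int, int, dict[int, float]]:
    """Rank candidate cluster numbers by the eigengap heuristic.

    Score(k) = lambda_{k+1} - lambda_k of the normalized-Laplacian spectrum
    (ascending). Returns (best_k, second_k, scores); deterministic, ties go
    to the smaller k.
    """
    n = fused.n
    if not (2 <= k_min < k_max < n):
        raise ValueError("need 2 <= k_min < k_max < n")
    A = _symmetric_affinity(fused)
    vals, _ = _laplacian_spectrum(A, min(k_max + 1, n))
    scores = {k: float(vals[k] - vals[k - 1]) for k in range(k_min, k_max + 1)}
    ranked = sorted(scores, key=lambda k: (-scores[k], k))
    return ranked[0], ranked[1], scores


def consensus_cluster(
    fused_builder,
    sample_ids: list[str],
    k: int,
    n_resamples: int = 100,
    subsample_frac: float = 0.8,
    seed: int = 0,
) -> tuple[np.ndarray, SubtypeResult]:
    """Consensus clustering over subsampled fuse -> cluster re-runs.

    ``fused_builder(indices)`` must return a fused :class:`AffinityNetwork`
    on the given sample indices (e.g. re-running SNF on subsampled
    expression, or subsetting a precomputed fused matrix). The consensus
    matrix entry (i, j) is the co-clustering frequency among resamples that
    contained both samples; final labels come from spectral clustering of
    the consensus matrix treated as an affinity.
    """
    if not (0.5 < subsample_frac <= 1.0):
        raise ValueError("subsample_frac must lie in (0.5, 1]")
    n = len(sample_ids)
    rng = np.random.default_rng(seed)
    together = np.zeros((n, n))
    counted = np.zeros((n, n))
    m = max(2, int(round(subsample_frac * n)))
    for b in range(n_resamples):
        idx = np.sort(rng.choice(n, size=min(m, n), replace=False))
        net = fused_builder(idx)
        res = spectral_cluster(net, k=min(k, len(idx)), seed=seed + b + 1)
        lab = res.labels
        same = lab[:, None] == lab[None, :]
        counted[np.ix_(idx, idx)] += 1.0
        together[np.ix_(idx, idx)] += same
    never = counted == 0
    np.fill_diagonal(never, False)
    if never.sum() > 0.01 * n * (n - 1):
        raise DataError("more than 1% of sample pairs were never co-sampled; "
                        "increase n_resamples or subsample_frac")
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(counted > 0, together / np.maximum(counted, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)

    cons_net = global_normalize(
        AffinityNetwork(consensus, list(sample_ids), "raw", {"K": max(2, n // 3)})
    )
    cons_net = AffinityNetwork(cons_net.matrix, list(sample_ids), "fused", cons_net.params)
    final = spectral_cluster(cons_net, k=k, seed=seed)
    final.consensus_matrix = consensus
    return consensus, final


def subset_builder(fused: AffinityNetwork):
    """A ``fused_builder`` that subsets one precomputed fused network."""

    def build(idx: np.ndarray) -> AffinityNetwork:
        sub = fused.matrix[np.ix_(idx, idx)]
        ids = [fused.sample_ids[i] for i in idx]
        net = global_normalize(AffinityNetwork(sub, ids, "raw", dict(fused.params)))
        return AffinityNetwork(net.matrix, ids, "fused", net.params)

    return build


def match_to_reference(labels: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Renumber cluster labels to best agree with a reference partition.

    Solves the assignment problem on the contingency table so that each
    cluster takes the reference label it overlaps most (one-to-one). Used
    when planted subtypes give clusters their identities, mirroring how
    discovered subtypes are named by their molecular characteristics.
    """
    from scipy.optimize import linear_sum_assignment

    labels = np.asarray(labels)
    reference = np.asarray(reference)
    ls = np.unique(labels)
    rs = np.unique(reference)
    table = np.array([[(reference[labels == l] == r).sum() for r in rs] for l in ls])
    rows, cols = linear_sum_assignment(-table)
    mapping = {ls[i]: rs[j] for i, j in zip(rows, cols)}
    leftovers = [r for r in rs if r not in mapping.values()]
    out = np.array([mapping.get(l, leftovers[0] if leftovers else l) for l in labels])
    return out


def adjusted_rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Chance-corrected agreement between two partitions (label-permutation invariant)."""
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(np.asarray(a).ravel(), np.asarray(b).ravel()))
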