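"""Consensus k-means engine.

Repeatedly clusters random subsamples of the samples (pItem) and genes
(pFeature) and aggregates how often each pair of samples lands in the same
k-means cluster, relative to how often the pair was drawn together.  The
resulting N x N consensus-index matrix (0-100 integer scale) is the evidence
on which cluster-number selection operates.  Eight subsampling settings
(pItem in {0.6, 0.7, 0.8, 0.9} x pFeature in {0.8, 1.0}), each with its own
seed and 100 repeats, form one "vote" over candidate k.

Within a process the same per-repeat subsample is clustered at every
candidate k (the convention of the underlying consensus-clustering scheme),
so :func:`run_consensus_multi` is the workhorse and :func:`run_consensus`
its single-k view.  Two purely numerical devices keep the engine fast
without changing results: k-means runs in float32, and when a subsample has
more features than samples it is replaced by an exact isometric embedding
(eigendecomposition of its Gram matrix), which preserves all pairwise
Euclidean distances and therefore the k-means objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

__all__ = [
    "ConsensusRunSetting",
    "ConsensusMatrix",
    "parameter_grid",
    "kmeans_labels",
    "run_consensus",
    "run_consensus_multi",
    "consensus_labels_from_index",
]

P_ITEMS = (0.6, 0.7, 0.8, 0.9)
P_FEATURES = (0.8, 1.0)

try:  # optional JIT of the Lloyd inner loop; the numpy path is equivalent
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _lloyd_jit_impl(Z, init, max_iter):  # pragma: no cover - jitted
    R, k = init.shape
    n, d = Z.shape
    best_wcss = np.inf
    best_labels = np.zeros(n, dtype=np.int64)
    Zsq = np.zeros(n, dtype=Z.dtype)
    for i in range(n):
        s = 0.0
        for j in range(d):
            s += Z[i, j] * Z[i, j]
        Zsq[i] = s
    labels = np.zeros(n, dtype=np.int64)
    prev = np.zeros(n, dtype=np.int64)
    centers = np.zeros((k, d), dtype=Z.dtype)
    counts = np.zeros(k, dtype=np.int64)
    csq = np.zeros(k, dtype=Z.dtype)
    for r in range(R):
        for j in range(k):
            centers[j] = Z[init[r, j]]
        for i in range(n):
            prev[i] = -1
        wcss = np.inf
        for _ in range(max_iter):
            prod = Z @ centers.T
            for j in range(k):
                s = 0.0
                for t in range(d):
                    s += centers[j, t] * centers[j, t]
                csq[j] = s
            changed = False
            wcss = 0.0
            worst = 0
            worst_d = -np.inf
            for i in range(n):
                bj = 0
                bd = csq[0] - 2.0 * prod[i, 0]
                for j in range(1, k):
                    dd = csq[j] - 2.0 * prod[i, j]
                    if dd < bd:
                        bd = dd
                        bj = j
                labels[i] = bj
                wcss += bd + Zsq[i]
                if bd + Zsq[i] > worst_d:
                    worst_d = bd + Zsq[i]
                    worst = i
                if bj != prev[i]:
                    changed = True
            if not changed:
                break
            for i in range(n):
                prev[i] = labels[i]
            centers[:] = 0.0
            counts[:] = 0
            for i in range(n):
                j = labels[i]
                counts[j] += 1
                for t in range(d):
                    centers[j, t] += Z[i, t]
            for j in range(k):
                if counts[j] > 0:
                    for t in range(d):
                        centers[j, t] /= counts[j]
                else:  # re-seed an empty cluster at the worst-fit point
                    centers[j] = Z[worst]
        if wcss < best_wcss:
            best_wcss = wcss
            best_labels[:] = labels
    return best_labels, best_wcss


if _HAVE_NUMBA:
    _lloyd_jit = _njit(cache=True, fastmath=True)(_lloyd_jit_impl)


@dataclass(frozen=True)
class ConsensusRunSetting:
    """One subsampling configuration of the consensus engine."""

    p_item: float
    p_feature: float
    repeats: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_item <= 1 and 0 < self.p_feature <= 1):
            raise ValueError("p_item and p_feature must be in (0, 1]")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class ConsensusMatrix:
    """Co-clustering evidence for one (setting, k) pair.

    ``index`` is ``round(100 * co_cluster / co_sample)`` with 0 where a pair
    was never co-drawn; ``labels`` is the consensus assignment (1..k)
    obtained by average-linkage clustering of ``1 - index/100``.
    """

    co_cluster: np.ndarray  # N x N int counts
    co_sample: np.ndarray  # N x N int counts
    index: np.ndarray  # N x N int, 0..100
    k: int
    labels: np.ndarray  # consensus assignment, values 1..k

    @property
    def n_samples(self) -> int:
        return self.index.shape[0]


def parameter_grid(
    seed: Optional[int] = None, repeats: int = 100
) -> List[ConsensusRunSetting]:
    """The eight pItem/pFeature settings with seeds derived from ``seed``.

    Seeds are drawn from a :class:`numpy.random.SeedSequence` spawned from
    the top-level seed, so a fixed top-level seed reproduces the whole grid.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(P_ITEMS) * len(P_FEATURES)) % (2**31)
    settings = []
    i = 0
    for p_item in P_ITEMS:
        for p_feature in P_FEATURES:
            settings.append(
                ConsensusRunSetting(
                    p_item=p_item,
                    p_feature=p_feature,
                    repeats=repeats,
                    seed=int(child_seeds[i]),
                )
            )
            i += 1
    return settings


def _lloyd_batch(
    Z: np.ndarray, Zsq: np.ndarray, k: int, init_idx: np.ndarray, max_iter: int
):
    """Lloyd iterations for all restarts at once; returns (labels, wcss).

    ``init_idx`` is (restarts, k) row indices of the initial centers.  Each
    restart stops once its labels are stable; distance and centroid updates
    are shared matmuls across the still-active restarts.  Returns the
    best-WCSS restart's labels.
    """
    n, d = Z.shape
    R = init_idx.shape[0]
    centers = Z[init_idx]  # (R, k, d)
    labels = np.full((R, n), -1)
    final_min = np.zeros((R, n), dtype=Z.dtype)
    active = np.arange(R)
    cols = np.arange(n)
    for _ in range(max_iter):
        ca = centers[active]  # (A, k, d)
        prod = Z @ ca.reshape(-1, d).T  # (n, A*k)
        csq = np.einsum("akd,akd->ak", ca, ca)
        part = (-2.0 * prod).reshape(n, len(active), k) + csq[None, :, :]
        new = part.argmin(axis=2)  # (n, A)
        part_min = part.min(axis=2)  # (n, A)
        same = (new == labels[active].T).all(axis=0)
        final_min[active] = part_min.T
        if same.any():
            labels[active[same]] = new[:, same].T
            active = active[~same]
            if active.size == 0:
                break
            new = new[:, ~same]
            part_min = part_min[:, ~same]
        labels[active] = new.T
        A = active.size
        flat = new + np.arange(A) * k  # (n, A)
        onehot = np.zeros((A * k, n), dtype=Z.dtype)
        onehot[flat.T, cols] = 1.0
        sums = (onehot @ Z).reshape(A, k, d)
        counts = onehot.sum(axis=1).reshape(A, k)
        nonempty = counts > 0
        upd = centers[active]
        upd[nonempty] = sums[nonempty] / counts[nonempty, None]
        for i, r in enumerate(active):  # re-seed empty clusters (rare)
            if not nonempty[i].all():
                upd[i, ~nonempty[i]] = Z[(part_min[:, i] + Zsq).argmax()]
        centers[active] = upd
    wcss = final_min.sum(axis=1) + Zsq.sum()
    best = int(wcss.argmin())
    return labels[best], float(wcss[best])


def kmeans_labels(
    Z: np.ndarray,
    k: int,
    restarts: int = 10,
    seed: Optional[int] = None,
    max_iter: int = 100,
) -> np.ndarray:
    """k-means (Lloyd, Euclidean) on rows of ``Z``; labels in 1..k.

    Runs ``restarts`` random initializations (centroids seeded at distinct
    data points) and keeps the partition with the lowest within-cluster sum
    of squares.  Raises if fewer than k distinct rows exist.
    """
    Z = np.ascontiguousarray(Z)
    if Z.dtype not in (np.float32, np.float64):
        Z = Z.astype(np.float64)
    n = Z.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples {n}")
    rng = np.random.default_rng(seed)
    init = np.stack([rng.choice(n, size=k, replace=False) for _ in range(restarts)])
    if _HAVE_NUMBA:
        best_labels, _ = _lloyd_jit(Z, init.astype(np.int64), max_iter)
    else:
        Zsq = np.einsum("ij,ij->i", Z, Z)
        best_labels, _ = _lloyd_batch(Z, Zsq, k, init, max_iter)
    if len(np.unique(best_labels)) < k:
        if np.unique(Z, axis=0).shape[0] < k:
            raise ValueError("fewer than k distinct points")
    return best_labels + 1


def _embed_isometric(S: np.ndarray) -> np.ndarray:
    """Replace samples x features ``S`` by an n-dimensional isometry.

    Centers the features, eigendecomposes the Gram matrix and returns
    ``V * sqrt(w)``: pairwise Euclidean distances (hence the k-means
    objective and its optima) are unchanged, but the dimensionality drops
    from n_features to n_samples.
    """
    S = S - S.mean(axis=0, keepdims=True)
    G = S @ S.T
    w, V = np.linalg.eigh(G)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def consensus_labels_from_index(index: np.ndarray, k: int) -> np.ndarray:
    """Consensus assignment: average-linkage on 1 - index/100 cut at k."""
    dist = 1.0 - np.asarray(index, dtype=float) / 100.0
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    link = average(squareform(dist, checks=False))
    return fcluster(link, t=k, criterion="maxclust")


def run_consensus_multi(
    Z: np.ndarray,
    ks: Sequence[int],
    setting: ConsensusRunSetting,
    restarts: int = 10,
    collect_draws: bool = False,
):
    """Consensus matrices for every k in ``ks`` under one setting.

    ``Z`` is samples x features (already z-scaled).  Each repeat draws
    ``ceil(p_item * N)`` samples and ``ceil(p_feature * G)`` features
    without replacement and clusters the same subsample at every k,
    incrementing the co-sampling count for every drawn pair and, per k, the
    co-clustering count for every co-labeled pair.  Deterministic given
    ``setting.seed``.  Returns ``{k: ConsensusMatrix}`` (plus the list of
    per-repeat sample draws when ``collect_draws``).
    """
    Z = np.asarray(Z, dtype=np.float64)
    n, g = Z.shape
    ks = sorted(set(int(k) for k in ks))
    if not ks or ks[0] < 2:
        raise ValueError("every k must be >= 2")
    n_item = int(np.ceil(setting.p_item * n))
    n_feat = int(np.ceil(setting.p_feature * g))
    if n_item < max(ks):
        raise ValueError(
            f"subsample of {n_item} samples cannot hold k={max(ks)} clusters"
        )
    rng = np.random.default_rng(setting.seed)
    co_sample = np.zeros((n, n), dtype=np.int32)
    co_cluster = {k: np.zeros((n, n), dtype=np.int32) for k in ks}
    draws = []
    for _ in range(setting.repeats):
        items = rng.choice(n, size=n_item, replace=False)
        feats = (
            rng.choice(g, size=n_feat, replace=False) if n_feat < g else np.arange(g)
        )
        sub = Z[np.ix_(items, feats)]
        if n_feat > n_item:
            sub = _embed_isometric(sub)
        sub32 = np.ascontiguousarray(sub, dtype=np.float32)
        co_sample[np.ix_(items, items)] += 1
        for k in ks:
            for attempt in range(10):
                try:
                    labels = kmeans_labels(
                        sub32, k, restarts=restarts, seed=int(rng.integers(2**31))
                    )
                    break
                except ValueError:
                    if attempt == 9:
                        raise ValueError(
                            "could not cluster a subsample with k distinct points"
                        )
            for j in range(1, k + 1):
                members = items[labels == j]
                if members.size:
                    co_cluster[k][np.ix_(members, members)] += 1
        if collect_draws:
            draws.append(items.copy())
    out: Dict[int, ConsensusMatrix] = {}
    for k in ks:
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(
                co_sample > 0, co_cluster[k] / np.maximum(co_sample, 1), 0.0
            )
        index = np.rint(100.0 * ratio).astype(np.int16)
        labels = consensus_labels_from_index(index, k)
        out[k] = ConsensusMatrix(
            co_cluster=co_cluster[k],
            co_sample=co_sample.copy(),
            index=index,
            k=k,
            labels=labels,
        )
    if collect_draws:
        return out, draws
    return out


def run_consensus(
    Z: np.ndarray,
    k: int,
    setting: ConsensusRunSetting,
    restarts: int = 10,
    collect_draws: bool = False,
):
    """Consensus matrix for a single k (see :func:`run_consensus_multi`)."""
    result = run_consensus_multi(
        Z, [k], setting, restarts=restarts, collect_draws=collect_draws
    )
    if collect_draws:
        matrices, draws = result
        return matrices[k], draws
    return result[k]
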