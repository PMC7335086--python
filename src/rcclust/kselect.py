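"""Cluster-number selection from consensus evidence.

For each candidate k the empirical CDF of off-diagonal consensus indices is
compared with the CDF a perfectly reproducible clustering would give: that
ideal curve is flat (slope 0) from c = 0 to c = 99 at the between-cluster
pair fraction.  A line is fitted through the CDF values within +-0.5 of the
ideal value (on the 0-100 scale) and trimmed from the low-c end until its
slope drops below threshold.  A k is admissible when

  a. line length  > ``min_line_length``   (default 30)
  b. line slope   < ``min_slope_deg``     (default 10 degrees)
  c. intra-cluster stability > 0.8  (mean consensus of within-cluster pairs)
  d. inter-cluster overlap   < 0.2  (mean consensus of between-cluster pairs)
  e. >= ``min_de_pct`` % of genes upregulated (FDR < 0.01) in some cluster

Ties among admissible k are broken by weights (+1 for slope <= 5 degrees,
+1 for length >= 40); each of the eight subsampling processes nominates the
max-weight k set, and the value most frequent across processes wins the
vote (frequency ties go to the smaller k; an empty vote returns 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .config_io import ExpressionMatrix, RCCConfig
from .consensus import ConsensusMatrix, ConsensusRunSetting, run_consensus_multi

__all__ = [
    "CDFCurve",
    "LineFit",
    "KEvaluation",
    "KDecision",
    "compute_maxK",
    "compute_cdf",
    "perfect_cdf_value",
    "fit_trim_line",
    "intra_cluster_stability",
    "inter_cluster_overlap",
    "de_gene_fraction",
    "evaluate_k",
    "best_k_for_process",
    "vote_optimal_k",
    "evaluate_process",
    "select_optimal_k",
]


@dataclass
class CDFCurve:
    """Empirical CDF of the off-diagonal consensus indices, c = 0..100."""

    values: np.ndarray  # length 101, values[c] = CDF(c)
    n_pairs: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        assert self.values.shape == (101,)


@dataclass
class LineFit:
    """Fitted/trimmed line through the near-ideal region of a CDF curve."""

    slope_deg: float
    length: float
    c_start: int
    c_end: int
    n_points: int
    valid: bool


@dataclass
class KEvaluation:
    """All admissibility statistics for one candidate k of one process."""

    k: int
    line: LineFit
    intra_stability: float
    inter_overlap: float
    de_fraction: float
    passes_a: bool
    passes_b: bool
    passes_c: bool
    passes_d: bool
    passes_e: bool
    weight: int

    @property
    def passes_all(self) -> bool:
        return (
            self.passes_a
            and self.passes_b
            and self.passes_c
            and self.passes_d
            and self.passes_e
        )


@dataclass
class KDecision:
    """Vote outcome across the eight subsampling processes."""

    best_ks_per_process: List[set]
    optimal_k: int  # 0 = no admissible k anywhere


def compute_maxK(n_samples: int) -> int:
    """Largest k to consider: min(10, floor(n/10)); < 2 means no clustering."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return min(10, n_samples // 10)


def compute_cdf(M: ConsensusMatrix) -> CDFCurve:
    """CDF(c) = fraction of unordered off-diagonal pairs with index <= c."""
    index = np.asarray(M.index)
    n = index.shape[0]
    iu = np.triu_indices(n, k=1)
    pairs = index[iu]
    n_pairs = pairs.size
    counts = np.bincount(np.clip(pairs, 0, 100).astype(int), minlength=101)
    values = np.cumsum(counts) / n_pairs
    return CDFCurve(values=values, n_pairs=n_pairs)


def perfect_cdf_value(cluster_sizes: Sequence[int]) -> float:
    """Between-cluster pair fraction: the flat level of an ideal CDF curve.

    For cluster sizes N_1..N_k summing to N this is
    ``1 - sum_i N_i (N_i - 1) / 2  /  (N (N - 1) / 2)``.
    """
    sizes = np.asarray(list(cluster_sizes), dtype=int)
    n = int(sizes.sum())
    if n < 2:
        raise ValueError("need at least 2 samples")
    within = float((sizes * (sizes - 1) / 2).sum())
    total = n * (n - 1) / 2
    return 1.0 - within / total


def _fit(cs: np.ndarray, ys: np.ndarray) -> float:
    """Least-squares slope of ys against cs (both on the 0-100 scale)."""
    if np.ptp(cs) == 0:
        return math.inf
    slope = np.polyfit(cs, ys, 1)[0]
    return math.degrees(math.atan(abs(slope)))


def fit_trim_line(
    curve: CDFCurve,
    cdfp: float,
    min_slope_deg: float = 10.0,
    min_line_length: float = 30.0,
) -> LineFit:
    """Fit a line through CDF values within +-0.5 of the ideal level.

    Works on the 0-100 x 0-100 scale (x = c in 0..99, y = 100 * CDF(c)).
    All c whose y lies within +-0.5 of ``100 * cdfp`` are selected; a
    least-squares line is fitted and, while its slope exceeds
    ``min_slope_deg``, the lowest-c point is dropped and the line refitted,
    stopping when the slope passes or the remaining span falls below
    ``min_line_length`` (then invalid).  Fewer than 2 selected points is
    also invalid.
    """
    y = 100.0 * curve.values[:100]
    cs = np.nonzero(np.abs(y - 100.0 * cdfp) <= 0.5)[0]

    def invalid() -> LineFit:
        c0 = int(cs[0]) if cs.size else 0
        c1 = int(cs[-1]) if cs.size else 0
        return LineFit(
            slope_deg=float("nan"),
            length=float(c1 - c0),
            c_start=c0,
            c_end=c1,
            n_points=int(cs.size),
            valid=False,
        )

    if cs.size < 2:
        return invalid()
    while True:
        slope = _fit(cs.astype(float), y[cs])
        length = float(cs[-1] - cs[0])
        if slope <= min_slope_deg:
            return LineFit(
                slope_deg=slope,
                length=length,
                c_start=int(cs[0]),
                c_end=int(cs[-1]),
                n_points=int(cs.size),
                valid=True,
            )
        cs = cs[1:]
        if cs.size < 2 or float(cs[-1] - cs[0]) < min_line_length:
            return invalid()


def _pair_means(M: ConsensusMatrix, labels: np.ndarray) -> Tuple[float, float]:
    index = np.asarray(M.index, dtype=float) / 100.0
    labels = np.asarray(labels)
    n = index.shape[0]
    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    vals = index[iu]
    intra = float(vals[same].mean()) if same.any() else 1.0
    inter = float(vals[~same].mean()) if (~same).any() else float("nan")
    return intra, inter


def intra_cluster_stability(M: ConsensusMatrix, labels: np.ndarray) -> float:
    """Mean consensus (0-1) over within-cluster pairs; 1.0 with no such pairs."""
    return _pair_means(M, labels)[0]


def inter_cluster_overlap(M: ConsensusMatrix, labels: np.ndarray) -> float:
    """Mean consensus (0-1) over between-cluster pairs (k >= 2 required)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("inter-cluster overlap needs >= 2 clusters")
    return _pair_means(M, labels)[1]


def de_gene_fraction(
    X_subset: ExpressionMatrix, labels: np.ndarray, fdr: float = 0.01
) -> float:
    """Fraction of genes upregulated (FDR < ``fdr``) in at least one cluster.

    One-vs-rest two-sided Wilcoxon rank-sum per gene with BH correction
    within each cluster comparison; "upregulated" means a positive mean
    difference.  Clusters with fewer than 2 members (on either side)
    contribute no genes.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 clusters")
    values = X_subset.values
    n_genes = values.shape[0]
    flagged = np.zeros(n_genes, dtype=bool)
    for cl in uniq:
        mask = labels == cl
        if mask.sum() < 2 or (~mask).sum() < 2:
            continue
        a = values[:, mask]
        b = values[:, ~mask]
        # constant genes make the rank-sum degenerate; mark them p=1
        degenerate = (a.min(axis=1) == a.max(axis=1)) & (
            a.min(axis=1) == b.min(axis=1)
        ) & (b.min(axis=1) == b.max(axis=1))
        with np.errstate(all="ignore"):
            stat = mannwhitneyu(a, b, axis=1, alternative="two-sided",
                                method="asymptotic")
        pvals = np.where(degenerate, 1.0, np.nan_to_num(stat.pvalue, nan=1.0))
        adjusted = multipletests(pvals, method="fdr_bh")[1]
        up = a.mean(axis=1) > b.mean(axis=1)
        flagged |= (adjusted < fdr) & up
    return float(flagged.sum()) / n_genes


def evaluate_k(
    M: ConsensusMatrix,
    labels: np.ndarray,
    X_subset: ExpressionMatrix,
    config: RCCConfig,
    lazy_de: bool = False,
) -> KEvaluation:
    """Apply admissibility criteria a-e and the weight rule to one k.

    With ``lazy_de=True`` the (comparatively expensive) differential-
    expression criterion is only computed once a-d all hold; a k already
    rejected on consensus geometry reports ``de_fraction = nan``.
    """
    curve = compute_cdf(M)
    sizes = np.bincount(np.asarray(labels))[1:]
    cdfp = perfect_cdf_value(sizes[sizes > 0])
    line = fit_trim_line(curve, cdfp, config.min_slope_deg, config.min_line_length)
    intra = intra_cluster_stability(M, labels)
    inter = inter_cluster_overlap(M, labels)
    min_de = config.resolved_min_de_pct(X_subset.n_samples) / 100.0

    a = bool(line.valid and line.length > config.min_line_length)
    b = bool(line.valid and line.slope_deg < config.min_slope_deg)
    c = intra > config.intra_stability_min
    d = inter < config.inter_overlap_max
    if lazy_de and not (a and b and c and d):
        de_frac = float("nan")
        e = False
    else:
        de_frac = de_gene_fraction(X_subset, labels, fdr=config.marker_fdr)
        e = de_frac > min_de
    weight = 0
    if a and b and c and d and e:
        weight = int(line.slope_deg <= config.weight_slope_deg) + int(
            line.length >= config.weight_line_length
        )
    return KEvaluation(
        k=M.k,
        line=line,
        intra_stability=intra,
        inter_overlap=inter,
        de_fraction=de_frac,
        passes_a=a,
        passes_b=b,
        passes_c=c,
        passes_d=d,
        passes_e=e,
        weight=weight,
    )


def best_k_for_process(evals: Sequence[KEvaluation]) -> set:
    """All admissible k achieving the maximum weight; empty if none pass."""
    passing = [e for e in evals if e.passes_all]
    if not passing:
        return set()
    top = max(e.weight for e in passing)
    return {e.k for e in passing if e.weight == top}


def vote_optimal_k(per_process: Sequence[set]) -> int:
    """Most frequent best-k across processes; none -> 0.

    Exact frequency ties resolve to the *larger* k: a coarser partition
    that is exactly as well supported is nested inside the finer one, so
    the finest equally-supported view is reported (on unequal group sizes
    a 2-way split can be perfectly consensus-stable and tie the true k in
    every process; picking the smaller k would systematically under-split).
    """
    pooled: Dict[int, int] = {}
    for s in per_process:
        for k in s:
            pooled[k] = pooled.get(k, 0) + 1
    if not pooled:
        return 0
    top = max(pooled.values())
    return max(k for k, freq in pooled.items() if freq == top)


def evaluate_process(
    Z: np.ndarray,
    X_subset: ExpressionMatrix,
    setting: ConsensusRunSetting,
    config: RCCConfig,
    max_k: int,
) -> Tuple[List[KEvaluation], Dict[int, ConsensusMatrix]]:
    """Run one subsampling process over k = 2..max_k and evaluate each k.

    All k share the same per-repeat subsample draws (the consensus engine's
    convention), so one pass over the repeats serves the whole k range.
    """
    matrices = run_consensus_multi(Z, range(2, max_k + 1), setting)
    evals = [
        evaluate_k(matrices[k], matrices[k].labels, X_subset, config, lazy_de=True)
        for k in sorted(matrices)
    ]
    return evals, matrices


def select_optimal_k(
    Z: np.ndarray,
    X_subset: ExpressionMatrix,
    settings: Sequence[ConsensusRunSetting],
    config: RCCConfig,
    max_k: int,
):
    """Full vote: evaluate every process, pool best-k sets, pick optimal k.

    Returns ``(decision, realizing_labels, diagnostics)`` where
    ``realizing_labels`` is the consensus partition (1..k) used to split at
    the voted k, taken from the nominating process with the longest (then
    flattest) fitted line for that k, and ``diagnostics`` is the per-process
    list of (setting, evaluations).
    """
    if max_k < 2:
        return KDecision(best_ks_per_process=[], optimal_k=0), None, []
    per_process: List[set] = []
    diagnostics = []
    all_matrices: List[Dict[int, ConsensusMatrix]] = []
    all_evals: List[List[KEvaluation]] = []
    for setting in settings:
        evals, matrices = evaluate_process(Z, X_subset, setting, config, max_k)
        per_process.append(best_k_for_process(evals))
        diagnostics.append((setting, evals))
        all_matrices.append(matrices)
        all_evals.append(evals)
    optimal = vote_optimal_k(per_process)
    decision = KDecision(best_ks_per_process=per_process, optimal_k=optimal)
    if optimal == 0:
        return decision, None, diagnostics
    # realizing partition: among nominating processes, longest then flattest line
    candidates = []
    for i, best_set in enumerate(per_process):
        if optimal in best_set:
            ev = next(e for e in all_evals[i] if e.k == optimal)
            candidates.append((ev.line.length, -ev.line.slope_deg, i))
    _, _, chosen = max(candidates)
    labels = all_matrices[chosen][optimal].labels
    return decision, labels, diagnostics
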