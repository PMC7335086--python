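import numpy as np
import pytest

from rcclust.config_io import ExpressionMatrix, RCCConfig
from rcclust.consensus import ConsensusMatrix
from rcclust.kselect import (
    CDFCurve,
    KEvaluation,
    LineFit,
    best_k_for_process,
    compute_cdf,
    compute_maxK,
    de_gene_fraction,
    evaluate_k,
    fit_trim_line,
    inter_cluster_overlap,
    intra_cluster_stability,
    perfect_cdf_value,
    vote_optimal_k,
)


def _matrix_from_index(index, k, labels):
    index = np.asarray(index, dtype=int)
    n = index.shape[0]
    reps = 100
    co_sample = np.full((n, n), reps, dtype=int)
    return ConsensusMatrix(
        co_cluster=(index * reps // 100).astype(int),
        co_sample=co_sample,
        index=index,
        k=k,
        labels=np.asarray(labels),
    )


def perfect_matrix(sizes):
    """Block-perfect consensus: within pairs at 100, between pairs at 0."""
    labels = np.repeat(np.arange(1, len(sizes) + 1), sizes)
    index = (labels[:, None] == labels[None, :]).astype(int) * 100
    return _matrix_from_index(index, len(sizes), labels)


def _random_index(n, seed):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 101, size=(n, n))
    index = np.triu(a, 1) + np.triu(a, 1).T
    np.fill_diagonal(index, 100)
    return index


class TestMaxK:
    @pytest.mark.parametrize("n,expected", [(300, 10), (98, 9), (25, 2), (19, 1), (5, 0)])
    def test_formula(self, n, expected):
        assert compute_maxK(n) == expected


class TestCDF:
    def test_all_zero_offdiagonal(self):
        M = _matrix_from_index(np.diag([100] * 5), 2, [1, 1, 1, 2, 2])
        curve = compute_cdf(M)
        assert (curve.values == 1.0).all()

    def test_two_perfect_pairs(self):
        M = perfect_matrix([2, 2])
        curve = compute_cdf(M)
        np.testing.assert_allclose(curve.values[:100], 4 / 6)
        assert curve.values[100] == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_pair_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        index = _random_index(n, seed)
        M = _matrix_from_index(index, 2, rng.integers(1, 3, size=n))
        curve = compute_cdf(M)
        for c in range(0, 101, 7):
            count = sum(
                1 for i in range(n) for j in range(i + 1, n) if index[i, j] <= c
            )
            assert curve.values[c] == pytest.approx(count / (n * (n - 1) / 2))

    def test_monotone_and_ends_at_one(self):
        for seed in range(5):
            index = _random_index(12, seed + 50)
            M = _matrix_from_index(index, 2, [1] * 6 + [2] * 6)
            curve = compute_cdf(M)
            assert (np.diff(curve.values) >= 0).all()
            assert curve.values[100] == 1.0


class TestPerfectCDFValue:
    def test_single_cluster(self):
        assert perfect_cdf_value([10]) == 0.0

    def test_all_singletons(self):
        assert perfect_cdf_value([1] * 8) == 1.0

    def test_two_equal_clusters_enumeration(self):
        # sizes [3,3]: 6 within pairs of 15 total -> 0.6 between fraction
        n = 6
        labels = [1, 1, 1, 2, 2, 2]
        between = sum(
            1
            for i in range(n)
            for j in range(i + 1, n)
            if labels[i] != labels[j]
        )
        assert perfect_cdf_value([3, 3]) == pytest.approx(between / 15) == 0.6

    @pytest.mark.parametrize("sizes", [[2, 5], [4, 4, 4], [1, 2, 3, 4]])
    def test_matches_pair_enumeration(self, sizes):
        labels = np.repeat(np.arange(len(sizes)), sizes)
        n = len(labels)
        between = sum(
            1
            for i in range(n)
            for j in range(i + 1, n)
            if labels[i] != labels[j]
        )
        total = n * (n - 1) / 2
        assert perfect_cdf_value(sizes) == pytest.approx(between / total)


def _oracle_trim(curve, cdfp, min_slope, min_len):
    """Exhaustive oracle: try every trailing-trim amount, return the longest
    line with slope <= threshold (mirrors the sequential low-c trimming)."""
    import math

    y = 100.0 * curve.values[:100]
    cs = np.nonzero(np.abs(y - 100.0 * cdfp) <= 0.5)[0]
    best = None
    for start in range(len(cs) - 1):
        pts = cs[start:]
        if pts[-1] - pts[0] < min_len and start > 0:
            break
        slope = abs(np.polyfit(pts.astype(float), y[pts], 1)[0])
        deg = math.degrees(math.atan(slope))
        if deg <= min_slope:
            best = (int(pts[0]), int(pts[-1]))
            break
    return best


class TestLineFit:
    def test_perfect_matrix_full_span(self):
        for sizes in ([4, 4], [3, 3, 3], [5, 2, 2]):
            M = perfect_matrix(sizes)
            curve = compute_cdf(M)
            line = fit_trim_line(curve, perfect_cdf_value(sizes))
            assert line.valid
            assert (line.c_start, line.c_end) == (0, 99)
            assert line.length == 99
            assert line.slope_deg == pytest.approx(0.0, abs=1e-9)

    def test_fewer_than_two_points_invalid(self):
        values = np.linspace(0, 1, 101)  # steep diagonal CDF
        curve = CDFCurve(values=values, n_pairs=45)
        line = fit_trim_line(curve, 0.0)  # band around 0 holds only c=0
        assert not line.valid

    def test_trimming_matches_exhaustive_oracle(self):
        # flat plateau at 0.6 with a noisy rise below c=20
        values = np.full(101, 0.6)
        values[:20] = np.linspace(0.3, 0.6, 20)
        values[100] = 1.0
        # perturb the plateau within the +-0.5 (0-100 scale) allowance
        rng = np.random.default_rng(0)
        values[20:100] += rng.uniform(-0.004, 0.004, 80)
        curve = CDFCurve(values=values, n_pairs=300)
        line = fit_trim_line(curve, 0.6, min_slope_deg=10, min_line_length=30)
        oracle = _oracle_trim(curve, 0.6, 10, 30)
        assert line.valid
        assert (line.c_start, line.c_end) == oracle

    def test_trim_failure_when_line_too_short(self):
        # steep everywhere inside the band -> trimming exhausts the length
        values = np.concatenate([np.linspace(0.595, 0.605, 100), [1.0]])
        curve = CDFCurve(values=values, n_pairs=100)
        line = fit_trim_line(curve, 0.6, min_slope_deg=0.001, min_line_length=98)
        assert not line.valid


class TestStabilityOverlap:
    def test_perfect_case(self):
        M = perfect_matrix([4, 4])
        assert intra_cluster_stability(M, M.labels) == 1.0
        assert inter_cluster_overlap(M, M.labels) == 0.0

    def test_all_zero_within(self):
        index = np.diag([100] * 4)
        M = _matrix_from_index(index, 2, [1, 1, 2, 2])
        assert intra_cluster_stability(M, M.labels) == 0.0

    def test_matches_bruteforce_means(self):
        index = _random_index(6, 3)
        labels = np.array([1, 1, 2, 2, 3, 3])
        M = _matrix_from_index(index, 3, labels)
        within, between = [], []
        for i in range(6):
            for j in range(i + 1, 6):
                (within if labels[i] == labels[j] else between).append(
                    index[i, j] / 100
                )
        assert intra_cluster_stability(M, labels) == pytest.approx(np.mean(within))
        assert inter_cluster_overlap(M, labels) == pytest.approx(np.mean(between))

    def test_overlap_requires_two_clusters(self):
        M = perfect_matrix([5])
        with pytest.raises(ValueError):
            inter_cluster_overlap(M, M.labels)


def _expr(values):
    g, n = values.shape
    return ExpressionMatrix(
        values, [f"g{i:03d}" for i in range(g)], [f"s{j:03d}" for j in range(n)]
    )


class TestDEFraction:
    def test_null_labels_give_near_zero(self):
        """Random labels on homogeneous data: FDR control keeps the flagged
        fraction essentially at zero."""
        fractions = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = _expr(rng.normal(5, 1, size=(100, 40)))
            labels = rng.integers(1, 3, size=40)
            if len(set(labels)) < 2:
                continue
            fractions.append(de_gene_fraction(X, labels))
        assert np.mean(fractions) < 0.01

    def test_power_at_strong_shift(self):
        """30% of genes shifted +3 log2 in one 30-sample cluster are found."""
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = _expr(rng.normal(5, 1, size=(100, 60)))
            labels = np.array([1] * 30 + [2] * 30)
            X.values[:30, :30] += 3.0
            assert de_gene_fraction(X, labels) >= 0.25

    def test_identical_expression_zero(self):
        X = _expr(np.full((20, 10), 5.0))
        assert de_gene_fraction(X, np.array([1] * 5 + [2] * 5)) == 0.0

    def test_requires_two_clusters(self):
        X = _expr(np.random.default_rng(0).normal(size=(10, 8)))
        with pytest.raises(ValueError):
            de_gene_fraction(X, np.ones(8, dtype=int))


class TestEvaluateK:
    def _strong_de_expr(self, sizes, seed=0):
        rng = np.random.default_rng(seed)
        n = sum(sizes)
        X = _expr(rng.normal(5, 1, size=(60, n)))
        start = 0
        for g, size in enumerate(sizes):
            X.values[g * 20 : (g + 1) * 20, start : start + size] += 4.0
            start += size
        return X

    def test_perfect_matrix_strong_de_full_pass(self):
        sizes = [10, 10]
        M = perfect_matrix(sizes)
        X = self._strong_de_expr(sizes)
        cfg = RCCConfig(data_type="bulk")
        ev = evaluate_k(M, M.labels, X, cfg)
        assert ev.passes_all
        assert ev.weight == 2  # slope 0 <= 5 and length 99 >= 40

    def test_perfect_matrix_no_de_fails_only_e(self):
        sizes = [10, 10]
        M = perfect_matrix(sizes)
        X = _expr(np.random.default_rng(1).normal(5, 1, size=(60, 20)))
        ev = evaluate_k(M, M.labels, X, RCCConfig(data_type="bulk"))
        assert ev.passes_a and ev.passes_b and ev.passes_c and ev.passes_d
        assert not ev.passes_e
        assert ev.weight == 0

    def test_raising_min_line_length_shrinks_passing_set(self):
        sizes = [10, 10]
        M = perfect_matrix(sizes)
        X = self._strong_de_expr(sizes)
        loose = evaluate_k(M, M.labels, X, RCCConfig(data_type="bulk", min_line_length=30))
        tight = evaluate_k(M, M.labels, X, RCCConfig(data_type="bulk", min_line_length=100))
        assert loose.passes_all and not tight.passes_all


def _eval_with_weight(k, weight, passes=True):
    line = LineFit(slope_deg=1.0, length=90, c_start=9, c_end=99, n_points=80, valid=True)
    return KEvaluation(
        k=k,
        line=line,
        intra_stability=0.95,
        inter_overlap=0.05,
        de_fraction=0.5,
        passes_a=passes,
        passes_b=passes,
        passes_c=passes,
        passes_d=passes,
        passes_e=passes,
        weight=weight if passes else 0,
    )


class TestBestKAndVote:
    def test_weight_rule_narrows_set(self):
        # k=2 passes but with weight 0; k=3,4,5 reach the top weight
        evals = [
            _eval_with_weight(2, 0),
            _eval_with_weight(3, 2),
            _eval_with_weight(4, 2),
            _eval_with_weight(5, 2),
            _eval_with_weight(6, 0, passes=False),
        ]
        assert best_k_for_process(evals) == {3, 4, 5}

    def test_no_passers_empty(self):
        evals = [_eval_with_weight(k, 0, passes=False) for k in (2, 3)]
        assert best_k_for_process(evals) == set()

    def test_single_passer(self):
        evals = [_eval_with_weight(2, 0, passes=False), _eval_with_weight(3, 1)]
        assert best_k_for_process(evals) == {3}

    def test_vote_mode(self):
        sets = [{4}, {4}, {3, 4}, {4, 5}, {4}, {4}, set(), {4}]
        assert vote_optimal_k(sets) == 4

    def test_vote_all_empty_returns_zero(self):
        assert vote_optimal_k([set()] * 8) == 0

    def test_vote_tie_breaks_to_larger(self):
        # equally frequent best ks: report the finest equally-supported view
        sets = [{3}, {4}, {3}, {4}]
        assert vote_optimal_k(sets) == 4
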