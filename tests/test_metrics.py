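"""Tests of correlation estimation and the FN^2 / wrong-sign metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ruvcoexp import (
    CorrelationSet,
    correlation_pvalues,
    ecdf_abs_correlations,
    fn_squared,
    metric_report,
    pearson_matrix,
    rank_differences,
    wrong_sign_pct,
)
from ruvcoexp.errors import (
    GeneSetMismatchError,
    InvalidInputError,
    UndefinedMetricError,
)

from conftest import make_expr


def corrset(matrix, label="test", m=10, prefix="g"):
    matrix = np.asarray(matrix, dtype=float)
    ids = [f"{prefix}{i}" for i in range(matrix.shape[0])]
    return CorrelationSet(matrix, ids, source_label=label, m_samples=m)


def brute_force_pearson(x, y):
    xd, yd = x - x.mean(), y - y.mean()
    return float(np.sum(xd * yd) / np.sqrt(np.sum(xd**2) * np.sum(yd**2)))


class TestPearson:
    def test_toy_pair(self):
        Y = make_expr(np.array([[1, 1], [2, 3], [3, 2], [4, 4]], dtype=float))
        cs = pearson_matrix(Y)
        assert cs.corr[0, 1] == pytest.approx(0.8)
        assert cs.corr[0, 0] == 1.0

    def test_affine_anticorrelation(self, rng):
        x = rng.standard_normal(6)
        Y = make_expr(np.column_stack([x, -2 * x + 7]))
        assert pearson_matrix(Y).corr[0, 1] == pytest.approx(-1.0)

    def test_affine_rescaling_invariance(self, rng):
        vals = rng.standard_normal((7, 4))
        scaled = vals * np.array([2.0, 0.5, 3.0, 1.5]) + np.array([1, -2, 0, 7])
        a = pearson_matrix(make_expr(vals)).corr
        b = pearson_matrix(make_expr(scaled)).corr
        np.testing.assert_allclose(a, b, atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_matches_brute_force(self, seed):
        r = np.random.default_rng(seed)
        vals = r.standard_normal((5, 5))
        cs = pearson_matrix(make_expr(vals))
        for i in range(5):
            for j in range(i + 1, 5):
                assert cs.corr[i, j] == pytest.approx(
                    brute_force_pearson(vals[:, i], vals[:, j]), abs=1e-12
                )

    def test_zero_variance_gene_excluded_with_warning(self, rng):
        vals = rng.standard_normal((6, 3))
        vals[:, 1] = 4.2
        with pytest.warns(UserWarning, match="zero-variance"):
            cs = pearson_matrix(make_expr(vals))
        assert cs.gene_ids == ["g0", "g2"]

    def test_too_few_samples(self, rng):
        with pytest.raises(InvalidInputError):
            pearson_matrix(make_expr(rng.standard_normal((2, 4))))


class TestFnSquared:
    def test_zero_when_equal(self):
        R = corrset([[1, 0.3], [0.3, 1]])
        assert fn_squared(R, R) == 0.0

    def test_single_pair_value(self):
        est = corrset([[1, 0.5], [0.5, 1]])
        truth = corrset([[1, 0.0], [0.0, 1]])
        assert fn_squared(est, truth) == pytest.approx(np.arctanh(0.5) ** 2)
        assert fn_squared(est, truth) == pytest.approx(0.30174, abs=1e-5)

    def test_uniform_shift_three_genes(self):
        z = np.eye(3)
        shifted = np.eye(3) + 0.1 * (1 - np.eye(3))
        val = fn_squared(corrset(shifted), corrset(z))
        assert val == pytest.approx(np.arctanh(0.1) ** 2)
        assert val == pytest.approx(0.010067, abs=1e-6)

    def test_symmetric_in_arguments_and_relabeling_invariant(self, rng):
        a = np.clip(rng.uniform(-0.8, 0.8, (4, 4)), -1, 1)
        a = (a + a.T) / 2; np.fill_diagonal(a, 1.0)
        b = np.clip(rng.uniform(-0.8, 0.8, (4, 4)), -1, 1)
        b = (b + b.T) / 2; np.fill_diagonal(b, 1.0)
        A, B = corrset(a), corrset(b)
        assert fn_squared(A, B) == pytest.approx(fn_squared(B, A))
        perm = [2, 0, 3, 1]
        Ap = CorrelationSet(a[np.ix_(perm, perm)], [f"g{i}" for i in perm], m_samples=10)
        assert fn_squared(Ap, B) == pytest.approx(fn_squared(A, B))

    def test_gene_set_mismatch(self):
        with pytest.raises(GeneSetMismatchError):
            fn_squared(corrset(np.eye(2)), corrset(np.eye(2), prefix="x"))

    def test_clipping_counted(self):
        est = corrset([[1, 1.0], [1.0, 1]])
        truth = corrset([[1, 0.0], [0.0, 1]])
        rep = metric_report(est, truth)
        assert rep.clipping_count == 1
        assert np.isfinite(rep.fn2)


class TestWrongSign:
    def test_zero_when_equal(self):
        R = corrset([[1, -0.3], [-0.3, 1]])
        assert wrong_sign_pct(R, R) == 0.0

    def test_full_flip_is_hundred(self):
        t = np.array([[1, 0.4, -0.2], [0.4, 1, 0.5], [-0.2, 0.5, 1]])
        assert wrong_sign_pct(corrset(-t + 2 * np.eye(3)), corrset(t)) == 100.0

    def test_enumeration_four_pairs(self):
        # truth signs (+, +, -, 0); estimates (+, -, -, +): 1 wrong of 3 eligible
        truth = np.eye(4)
        truth[0, 1] = truth[1, 0] = 0.5    # +  est +
        truth[0, 2] = truth[2, 0] = 0.3    # +  est -
        truth[0, 3] = truth[3, 0] = -0.4   # -  est -
        truth[1, 2] = truth[2, 1] = 0.0    # 0  est +  (excluded)
        est = np.eye(4)
        est[0, 1] = est[1, 0] = 0.6
        est[0, 2] = est[2, 0] = -0.1
        est[0, 3] = est[3, 0] = -0.2
        est[1, 2] = est[2, 1] = 0.7
        assert wrong_sign_pct(corrset(est), corrset(truth)) == pytest.approx(100 / 3)

    def test_sign_flip_invariance(self, rng):
        t = np.array([[1, 0.4], [0.4, 1]])
        e = np.array([[1, -0.2], [-0.2, 1]])
        assert wrong_sign_pct(corrset(e), corrset(t)) == wrong_sign_pct(
            corrset(-e + 2 * np.eye(2)), corrset(-t + 2 * np.eye(2))
        )

    def test_all_null_truth_undefined(self):
        with pytest.raises(UndefinedMetricError):
            wrong_sign_pct(corrset([[1, 0.5], [0.5, 1]]), corrset(np.eye(2)))

    def test_zero_estimate_on_nonzero_truth_counts_wrong(self):
        est = corrset(np.eye(2))
        truth = corrset([[1, 0.5], [0.5, 1]])
        assert wrong_sign_pct(est, truth) == 100.0


class TestPvalues:
    def test_r_zero_gives_one(self):
        cs = corrset(np.eye(2), m=12)
        assert correlation_pvalues(cs)[0, 1] == pytest.approx(1.0)

    def test_r_near_one_gives_near_zero(self):
        cs = corrset([[1, 0.999999], [0.999999, 1]], m=12)
        assert correlation_pvalues(cs)[0, 1] < 1e-9

    def test_reference_t_distribution_value(self):
        # r = 0.5, m = 12: t = 0.5*sqrt(10/0.75) ~ 1.8257, p ~ 0.0977
        cs = corrset([[1, 0.5], [0.5, 1]], m=12)
        assert correlation_pvalues(cs)[0, 1] == pytest.approx(0.0977, abs=2e-4)

    def test_too_few_samples(self):
        with pytest.raises(InvalidInputError):
            correlation_pvalues(corrset(np.eye(2), m=3))


class TestEcdf:
    def test_degenerate_step(self):
        c = np.full((3, 3), 0.5); np.fill_diagonal(c, 1.0)
        ecdf = ecdf_abs_correlations(corrset(c))
        assert ecdf(0.49) == 0.0
        assert ecdf(0.5) == 1.0

    def test_counting(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.1
        c[0, 2] = c[2, 0] = -0.2
        c[1, 2] = c[2, 1] = 0.4
        ecdf = ecdf_abs_correlations(corrset(c))
        assert ecdf(0.25) == pytest.approx(2 / 3)
        assert ecdf(1.0) == 1.0

    def test_table_is_sorted(self, rng):
        m = rng.uniform(-1, 1, (5, 5)); m = (m + m.T) / 2; np.fill_diagonal(m, 1)
        tab = ecdf_abs_correlations(corrset(np.clip(m, -1, 1))).table()
        assert tab["abs_corr"].is_monotonic_increasing
        assert tab["cum_fraction"].iloc[-1] == 1.0


class TestRankDifferences:
    def test_identical_sets_give_zero(self, rng):
        m = rng.uniform(-0.9, 0.9, (4, 4)); m = (m + m.T) / 2; np.fill_diagonal(m, 1)
        cs = corrset(m)
        out = rank_differences(cs, cs, [("g0", "g1"), ("g2", "g3")])
        assert (out["rank_difference"] == 0).all()

    def test_weakest_to_strongest(self):
        ref = np.eye(3)
        ref[0, 1] = ref[1, 0] = 0.9
        ref[0, 2] = ref[2, 0] = 0.5
        ref[1, 2] = ref[2, 1] = 0.1   # weakest, rank 3
        cln = np.eye(3)
        cln[0, 1] = cln[1, 0] = 0.2
        cln[0, 2] = cln[2, 0] = 0.1
        cln[1, 2] = cln[2, 1] = 0.8   # strongest, rank 1
        out = rank_differences(corrset(ref), corrset(cln), [("g1", "g2")])
        assert out["rank_difference"].iloc[0] == 2  # N-1 with N=3 pairs

    def test_enumeration_against_manual_ranks(self):
        # |r| reference (g0g1, g0g2, g1g2) = (0.9, 0.5, 0.4); cleaned (0.2, 0.8, 0.7)
        ref = np.eye(3)
        ref[0, 1] = ref[1, 0] = 0.9
        ref[0, 2] = ref[2, 0] = 0.5
        ref[1, 2] = ref[2, 1] = 0.4
        cln = np.eye(3)
        cln[0, 1] = cln[1, 0] = 0.2
        cln[0, 2] = cln[2, 0] = 0.8
        cln[1, 2] = cln[2, 1] = 0.7
        out = rank_differences(corrset(ref), corrset(cln), [("g0", "g2")])
        # reference rank 2 -> cleaned rank 1: difference +1
        assert out["rank_difference"].iloc[0] == 1

    def test_missing_focus_pair(self):
        cs = corrset(np.eye(3))
        with pytest.raises(InvalidInputError):
            rank_differences(cs, cs, [("g0", "nope")])
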