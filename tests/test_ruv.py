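"""Unit and property tests for the four-step cleaning procedure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import subspace_angles

from ruvcoexp import (
    ControlGeneSet,
    RUVFit,
    RUVParams,
    SimulationDesign,
    center_genes,
    estimate_alpha_ridge,
    fit_unwanted_variation,
    generate_dataset,
    pearson_matrix,
    remove_unwanted_variation,
    ruv_random_clean,
    suggest_nu_grid,
)
from ruvcoexp.errors import (
    DegenerateInputError,
    InvalidInputError,
    InvalidParameterError,
    NumericalRankError,
)

from conftest import make_expr


def _centered(rng, m, n):
    Y = make_expr(rng.standard_normal((m, n)))
    return center_genes(Y)


class TestCenterGenes:
    def test_two_sample_gene(self):
        out = center_genes(make_expr([[1.0, 5.0], [3.0, 5.0]]))
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 1.0])
        np.testing.assert_allclose(out.values[:, 1], [0.0, 0.0])
        assert out.centered

    def test_idempotent(self, small_matrix):
        once = center_genes(small_matrix)
        twice = center_genes(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-14)

    def test_gene_means_zero(self, small_matrix):
        out = center_genes(small_matrix)
        assert np.abs(out.values.mean(axis=0)).max() < 1e-10

    def test_single_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            center_genes(make_expr([[1.0, 2.0]]))


class TestFactorFit:
    def test_rank_one_control_block(self, rng):
        u = rng.standard_normal(6)
        u -= u.mean()
        v = rng.standard_normal(3)
        vals = np.column_stack([np.outer(u, v), rng.standard_normal((6, 2))])
        Y = make_expr(vals)
        Ystar = center_genes(Y)
        controls = ControlGeneSet(Y.gene_ids[:3], role="negative")
        fit = fit_unwanted_variation(Ystar, controls, RUVParams(k=1))
        angles = subspace_angles(fit.W_hat, u[:, None])
        assert angles.max() < 1e-8

    def test_gram_eigendecomposition_oracle(self, rng):
        Ystar = _centered(rng, 6, 7)
        controls = ControlGeneSet(Ystar.gene_ids[:4], role="negative")
        fit = fit_unwanted_variation(Ystar, controls, RUVParams(k=2))
        Yc = Ystar.values[:, :4]
        evals, evecs = np.linalg.eigh(Yc @ Yc.T)
        top = evecs[:, np.argsort(evals)[::-1][:2]]
        assert subspace_angles(fit.W_hat, top).max() < 1e-6

    def test_basis_orthonormal_and_singvals_sorted(self, rng):
        Ystar = _centered(rng, 10, 20)
        controls = ControlGeneSet(Ystar.gene_ids[:8], role="negative")
        fit = fit_unwanted_variation(Ystar, controls, RUVParams(k=4))
        np.testing.assert_allclose(fit.basis.T @ fit.basis, np.eye(4), atol=1e-8)
        assert np.all(np.diff(fit.singular_values) <= 1e-12)
        # W_hat = basis * singular values
        np.testing.assert_allclose(fit.W_hat, fit.basis * fit.singular_values[:4])

    def test_k_zero_gives_empty_factors_and_identity_cleaning(self, rng):
        Ystar = _centered(rng, 6, 8)
        controls = ControlGeneSet(Ystar.gene_ids[:5], role="negative")
        fit = fit_unwanted_variation(Ystar, controls, RUVParams(k=0))
        assert fit.W_hat.shape == (6, 0)
        fit = estimate_alpha_ridge(Ystar, fit, 0.0)
        out = remove_unwanted_variation(Ystar, fit)
        np.testing.assert_allclose(out.values, Ystar.values, atol=1e-12)

    def test_k_too_large_rejected(self, rng):
        Ystar = _centered(rng, 6, 8)
        controls = ControlGeneSet(Ystar.gene_ids[:3], role="negative")
        with pytest.raises(InvalidParameterError):
            fit_unwanted_variation(Ystar, controls, RUVParams(k=4))

    def test_zero_control_block_degenerate(self):
        vals = np.column_stack([np.zeros((4, 2)), [[1.0], [-1.0], [2.0], [-2.0]]])
        Ystar = make_expr(vals, centered=True)
        controls = ControlGeneSet(Ystar.gene_ids[:2], role="negative")
        with pytest.raises(DegenerateInputError):
            fit_unwanted_variation(Ystar, controls, RUVParams(k=1))

    def test_requires_negative_role(self, rng):
        Ystar = _centered(rng, 6, 8)
        controls = ControlGeneSet(Ystar.gene_ids[:3], role="positive")
        with pytest.raises(InvalidParameterError):
            fit_unwanted_variation(Ystar, controls, RUVParams(k=1))


def _manual_fit(W, control_ids=("c0",)):
    """RUVFit wrapper around an arbitrary factor matrix."""
    return RUVFit(
        W_hat=W, basis=W, singular_values=np.linalg.svd(W, compute_uv=False),
        params=RUVParams(k=W.shape[1]), control_ids=list(control_ids),
    )


class TestRidge:
    def test_augmented_least_squares_oracle_toy(self, rng):
        W = rng.standard_normal((5, 3))
        Ystar = _centered(rng, 5, 4)
        fit = estimate_alpha_ridge(Ystar, _manual_fit(W), nu=2.0)
        aug_A = np.vstack([W, np.sqrt(2.0) * np.eye(3)])
        aug_b = np.vstack([Ystar.values, np.zeros((3, 4))])
        expected = np.linalg.lstsq(aug_A, aug_b, rcond=None)[0]
        np.testing.assert_allclose(fit.alpha_hat, expected, atol=1e-8)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000), nu=st.floats(0.01, 50.0))
    def test_ridge_matches_augmented_system(self, seed, nu):
        r = np.random.default_rng(seed)
        m, k, n = r.integers(3, 9), r.integers(1, 4), r.integers(1, 7)
        W = r.standard_normal((m, k))
        Ystar = center_genes(make_expr(r.standard_normal((m, n))))
        fit = estimate_alpha_ridge(Ystar, _manual_fit(W), nu=float(nu))
        aug_A = np.vstack([W, np.sqrt(nu) * np.eye(k)])
        aug_b = np.vstack([Ystar.values, np.zeros((k, n))])
        expected = np.linalg.lstsq(aug_A, aug_b, rcond=None)[0]
        np.testing.assert_allclose(fit.alpha_hat, expected, atol=1e-8)

    def test_huge_nu_shrinks_alpha_to_zero(self, rng):
        Ystar = _centered(rng, 8, 10)
        controls = ControlGeneSet(Ystar.gene_ids[:6], role="negative")
        fit = fit_unwanted_variation(Ystar, controls, RUVParams(k=2))
        nu = 1e12 * fit.singular_values[0] ** 2
        fit = estimate_alpha_ridge(Ystar, fit, nu)
        assert np.abs(fit.alpha_hat).max() < 1e-9
        out = remove_unwanted_variation(Ystar, fit)
        np.testing.assert_allclose(out.values, Ystar.values, atol=1e-6)

    def test_zero_nu_with_orthonormal_basis_is_projection(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((6, 2)))
        Ystar = _centered(rng, 6, 5)
        fit = estimate_alpha_ridge(Ystar, _manual_fit(Q), nu=0.0)
        np.testing.assert_allclose(fit.alpha_hat, Q.T @ Ystar.values, atol=1e-10)

    def test_rank_deficient_without_ridge_raises(self, rng):
        W = np.column_stack([rng.standard_normal(5), np.zeros(5)])
        Ystar = _centered(rng, 5, 3)
        with pytest.raises(NumericalRankError):
            estimate_alpha_ridge(Ystar, _manual_fit(W), nu=0.0)

    def test_cleaning_distance_decreases_with_nu(self, rng):
        """Beyond the top squared singular value the output approaches Y*."""
        Ystar = _centered(rng, 10, 15)
        controls = ControlGeneSet(Ystar.gene_ids[:10], role="negative")
        base = fit_unwanted_variation(Ystar, controls, RUVParams(k=3))
        top2 = base.singular_values[0] ** 2
        dists = []
        for mult in [1.0, 10.0, 100.0, 1000.0]:
            fit = estimate_alpha_ridge(Ystar, base, nu=mult * top2)
            out = remove_unwanted_variation(Ystar, fit)
            dists.append(np.abs(out.values - Ystar.values).max())
        assert all(a > b for a, b in zip(dists, dists[1:]))


class TestRemoval:
    def test_exact_cancellation_in_span(self, rng):
        W = rng.standard_normal((10, 2))
        W -= W.mean(axis=0)
        alpha = rng.standard_normal((2, 6))
        Ystar = make_expr(W @ alpha, centered=True)
        controls = ControlGeneSet(Ystar.gene_ids, role="negative")
        cleaned, _ = ruv_random_clean(Ystar, controls, RUVParams(k=2, nu=0.0))
        assert np.abs(cleaned.values).max() < 1e-8

    def test_output_recentered(self, rng):
        Ystar = _centered(rng, 9, 11)
        controls = ControlGeneSet(Ystar.gene_ids[:7], role="negative")
        cleaned, _ = ruv_random_clean(Ystar, controls, RUVParams(k=3, nu=1.0))
        assert np.abs(cleaned.values.mean(axis=0)).max() < 1e-10

    def test_shape_mismatch_rejected(self, rng):
        Ystar = _centered(rng, 6, 5)
        other = _centered(rng, 7, 5)
        controls = ControlGeneSet(Ystar.gene_ids[:4], role="negative")
        fit = fit_unwanted_variation(Ystar, controls, RUVParams(k=2))
        fit = estimate_alpha_ridge(Ystar, fit, 1.0)
        with pytest.raises(InvalidInputError):
            remove_unwanted_variation(other, fit)

    def test_missing_alpha_rejected(self, rng):
        Ystar = _centered(rng, 6, 5)
        controls = ControlGeneSet(Ystar.gene_ids[:4], role="negative")
        fit = fit_unwanted_variation(Ystar, controls, RUVParams(k=2))
        with pytest.raises(InvalidInputError):
            remove_unwanted_variation(Ystar, fit)


class TestFullProcedure:
    def test_k_zero_equals_centering(self, small_matrix):
        controls = ControlGeneSet(small_matrix.gene_ids[:6], role="negative")
        cleaned, fit = ruv_random_clean(small_matrix, controls, RUVParams(k=0))
        np.testing.assert_allclose(cleaned.values, center_genes(small_matrix).values)
        assert fit.k == 0

    def test_null_simulation_correlations_center_at_zero(self):
        design = SimulationDesign(n_signal=0, block_sizes=(), seed=77)
        Y, _, controls = generate_dataset(design)
        cleaned, _ = ruv_random_clean(Y, controls, RUVParams(k=3, nu=1e-3), relative_nu=True)
        corr = pearson_matrix(cleaned)
        assert abs(corr.offdiag_values().mean()) < 0.02

    def test_cleaned_controls_variance_near_random_noise(self):
        """With true controls and correct k, cleaning strips the systematic
        component: control-gene variance falls to about Var(eps)."""
        design = SimulationDesign(seed=123)
        Y, truth, controls = generate_dataset(design)
        cleaned, _ = ruv_random_clean(Y, controls, RUVParams(k=3, nu=1e-3), relative_nu=True)
        idx = cleaned.gene_indices(controls.ids)
        var_cleaned = cleaned.values[:, idx].var(axis=0, ddof=1).mean()
        _, sigma_eps = design.resolved_scales()
        assert var_cleaned < 1.1 * sigma_eps ** 2

    def test_variance_removed_and_nu_grid(self, rng):
        Ystar = _centered(rng, 12, 20)
        controls = ControlGeneSet(Ystar.gene_ids[:10], role="negative")
        cleaned, fit = ruv_random_clean(Ystar, controls, RUVParams(k=2, nu=0.0))
        assert 0.0 < fit.variance_removed(Ystar) <= 1.0
        grid = suggest_nu_grid(fit)
        assert grid[0] == 0.0 and np.all(np.diff(grid) > 0)
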