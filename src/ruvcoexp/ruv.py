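"""RUV-random cleaning for gene-gene correlation estimation.

The data are modelled as Y = X beta + W alpha + eps, where X beta is the
biological signal of interest, W alpha is systematic (unwanted) variation
spanning k latent factors, and eps is i.i.d. random noise. Negative-control
genes -- genes assumed to carry no signal, so that Y_c = W alpha_c + eps_c --
identify the structure of W. The cleaning procedure has four steps:

1. center every gene across samples: Y* = (I - J/m) Y;
2. estimate W by SVD factor analysis of the centered control submatrix Y*_c;
3. ridge-regress Y* on the estimated factors:
   alpha_hat = (W'W + nu I_k)^(-1) W' Y*;
4. subtract W alpha_hat from Y*.

The ridge penalty nu controls how aggressively the noise (and, if signal and
noise are correlated, some signal) is removed; nu -> infinity leaves the data
untouched. Factor scores are scaled by their singular values (W_hat = U_k D_k),
so nu is on the scale of squared singular values of the control submatrix.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import ControlGeneSet, ExpressionMatrix, RUVFit, RUVParams
from .errors import (
    DegenerateInputError,
    InvalidInputError,
    InvalidParameterError,
    NumericalRankError,
)

logger = logging.getLogger(__name__)

ORTHONORMAL_TOL = 1e-8


def center_genes(Y: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's mean across samples (step 1).

    Idempotent; requires at least two samples. The intercept is deliberately
    not estimated through the factor model because doing so can introduce
    spurious correlations, and correlation measures discard offsets anyway.
    """
    if Y.n_samples < 2:
        raise InvalidInputError("centering requires at least 2 samples")
    centered = Y.values - Y.values.mean(axis=0, keepdims=True)
    # second pass guards against float accumulation on long matrices
    centered -= centered.mean(axis=0, keepdims=True)
    return Y.with_values(centered, centered=True)


def fit_unwanted_variation(
    Ystar: ExpressionMatrix, controls: ControlGeneSet, params: RUVParams
) -> RUVFit:
    """Estimate the unwanted-variation factors from negative controls (step 2).

    Returns a fit whose ``W_hat = U_k D_k`` holds the k leading left singular
    vectors of the centered control submatrix scaled by their singular values;
    the orthonormal basis U_k and the full singular-value spectrum (for scree
    inspection when choosing k) are retained.
    """
    if not Ystar.centered:
        raise InvalidInputError("fit_unwanted_variation requires centered data")
    if controls.role != "negative":
        raise InvalidParameterError(
            f"factor fitting needs negative controls, got role={controls.role!r}"
        )
    idx = controls.indices_in(Ystar)
    m, n_c = Ystar.n_samples, len(idx)
    if params.k > min(m, n_c):
        raise InvalidParameterError(
            f"k={params.k} exceeds min(m={m}, |c|={n_c})"
        )
    Yc = Ystar.values[:, idx]
    if not np.any(Yc):
        raise DegenerateInputError("control submatrix is exactly zero")
    U, s, _ = np.linalg.svd(Yc, full_matrices=False)
    k = params.k
    basis = U[:, :k]
    W_hat = basis * s[:k]
    return RUVFit(
        W_hat=W_hat,
        basis=basis,
        singular_values=s,
        params=params,
        control_ids=list(controls.ids),
    )


def estimate_alpha_ridge(
    Ystar: ExpressionMatrix, fit: RUVFit, nu: float | None = None
) -> RUVFit:
    """Ridge-regress the full centered matrix on the estimated factors (step 3).

    alpha_hat = (W'W + nu I_k)^(-1) W' Y*. The "+ nu" of the ridge estimator
    is read as nu times the k x k identity, the only dimensionally consistent
    interpretation. The regression uses all n genes, not just the controls.
    """
    if not Ystar.centered:
        raise InvalidInputError("estimate_alpha_ridge requires centered data")
    if nu is None:
        nu = fit.params.nu
    if nu < 0:
        raise InvalidParameterError(f"nu must be >= 0, got {nu}")
    W = fit.W_hat
    k = W.shape[1]
    if k == 0:
        fit.alpha_hat = np.zeros((0, Ystar.n_genes))
        fit.params = RUVParams(k=0, nu=float(nu))
        return fit
    G = W.T @ W + nu * np.eye(k)
    # W = U_k D_k, so G = D_k^2 + nu I; singular iff nu == 0 and some D_kk == 0
    diag = np.diag(G)
    if np.min(diag) <= max(np.max(diag), 1.0) * np.finfo(float).eps:
        raise NumericalRankError(
            "W'W + nu*I is numerically singular (rank-deficient factors with "
            "nu=0); use a ridge penalty nu > 0"
        )
    fit.alpha_hat = np.linalg.solve(G, W.T @ Ystar.values)
    fit.params = RUVParams(k=fit.params.k, nu=float(nu))
    return fit


def remove_unwanted_variation(Ystar: ExpressionMatrix, fit: RUVFit) -> ExpressionMatrix:
    """Subtract the fitted unwanted variation (step 4) and re-center.

    Since Y* and the columns of W_hat are centered, subtracting W alpha_hat
    can move gene means only at floating-point level; re-centering is
    numerical hygiene, not a model step.
    """
    if fit.alpha_hat is None:
        raise InvalidInputError("fit has no alpha_hat; run estimate_alpha_ridge first")
    if fit.W_hat.shape[0] != Ystar.n_samples or fit.alpha_hat.shape[1] != Ystar.n_genes:
        raise InvalidInputError(
            f"fit shapes {fit.W_hat.shape} x {fit.alpha_hat.shape} do not match "
            f"data ({Ystar.n_samples}, {Ystar.n_genes})"
        )
    cleaned = Ystar.values - fit.W_hat @ fit.alpha_hat
    drift = float(np.abs(cleaned.mean(axis=0)).max(initial=0.0))
    scale = float(np.abs(cleaned).max(initial=1.0))
    if drift > 1e-6 * max(scale, 1.0):  # pragma: no cover - model violation guard
        logger.warning("post-removal gene-mean drift %.3g exceeds float noise", drift)
    cleaned = cleaned - cleaned.mean(axis=0, keepdims=True)
    return Ystar.with_values(cleaned, centered=True)


def ruv_random_clean(
    Y: ExpressionMatrix, controls: ControlGeneSet, params: RUVParams,
    relative_nu: bool = False,
) -> tuple[ExpressionMatrix, RUVFit]:
    """Run the full four-step cleaning procedure.

    Returns the cleaned, gene-centered matrix and the fit (factors,
    coefficients, singular values). With k = 0 the output equals the centered
    input. With ``relative_nu`` the penalty is ``params.nu`` times the squared
    leading singular value of the control submatrix -- a scale-free way of
    asking for a "small" ridge (e.g. nu=1e-3).
    """
    Ystar = center_genes(Y)
    fit = fit_unwanted_variation(Ystar, controls, params)
    nu = params.nu
    if relative_nu and fit.singular_values.size:
        nu = params.nu * float(fit.singular_values[0]) ** 2
    fit = estimate_alpha_ridge(Ystar, fit, nu)
    cleaned = remove_unwanted_variation(Ystar, fit)
    logger.info(
        "RUV-random: k=%d nu=%.4g |controls|=%d variance_removed=%.3f",
        params.k, nu, len(controls), fit.variance_removed(Ystar),
    )
    return cleaned, fit


def suggest_nu_grid(fit: RUVFit, n_points: int = 7) -> np.ndarray:
    """A candidate grid for the ridge penalty.

    Spans 0 and 1e-4 ... 1e2 times the squared leading singular value of the
    control submatrix (the natural scale of W'W). Candidates should be judged
    with the diagnostics module: random-gene correlation density centered at
    zero, positive-control density shifted positive.
    """
    if fit.singular_values.size == 0:  # pragma: no cover
        return np.array([0.0])
    top = float(fit.singular_values[0]) ** 2
    grid = top * np.logspace(-4, 2, n_points)
    return np.concatenate([[0.0], grid])
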