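"""Seeded generator for expression data with known correlation structure.

The generator draws from the linear model Y = X beta + W alpha + eps used
throughout the package. Signal genes are organized in blocks: every gene in a
block loads on the block's shared standard-normal factor with a loading drawn
from +/- Uniform(loading_range), and on a private factor of its own scaled so
that the true correlation between any two genes of a block has absolute value
exactly ``within_block_corr`` (sign = product of loading signs). Genes in
different blocks, and all non-signal genes, are truly uncorrelated. The
analytic truth follows directly from beta because all factor columns are
independent standard normals.

Unwanted variation W spans ``k_true`` latent factors. Dependence between
signal and noise is induced by linear mixing,

    W = sqrt(c) * X_shared A + sqrt(1 - c) * G,

with A a random column-unit-norm mixing matrix over the shared signal factors
and G fresh standard normal; c = 0 gives W independent of X in expectation,
and each W column keeps unit variance for any c.

Noise scales default to a noise-dominant regime: per-gene Var(W alpha) is
``noise_to_signal`` (default 12) times the per-gene signal variance and
Var(eps) is ``eps_to_signal`` (default 0.5) times it. Under these defaults
raw-data correlation estimates have a nearly random sign for truly correlated
pairs (~48 % wrong sign at m = 180), the regime this package's benchmarks
target. Measured background noise (scanner floor etc.) is deliberately not
simulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import ControlGeneSet, CorrelationSet, ExpressionMatrix
from .errors import DegenerateInputError, InvalidParameterError

logger = logging.getLogger(__name__)


@dataclass
class SimulationDesign:
    """Parameters of one simulated dataset; all defaults overridable.

    The default design -- 180 samples, 500 genes of which 250 signal genes in
    10 blocks of 25 with within-block |r| = 0.35, 3 unwanted factors, noise
    12x and random error 0.5x the signal variance -- is the configuration the
    package's benchmark suite runs.
    """

    m: int = 180
    n: int = 500
    n_signal: int = 250
    block_sizes: tuple[int, ...] = (25,) * 10
    loading_range: tuple[float, float] = (0.3, 1.0)
    within_block_corr: float = 0.35
    k_true: int = 3
    noise_to_signal: float = 12.0
    eps_to_signal: float = 0.5
    sigma_alpha: float | None = None
    sigma_eps: float | None = None
    noise_signal_mix: float = 0.0
    control_fraction: float = 1.0
    contaminate_controls: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal > self.n:
            raise InvalidParameterError("n_signal must be <= n")
        if sum(self.block_sizes) != self.n_signal:
            raise InvalidParameterError(
                f"block_sizes sum to {sum(self.block_sizes)}, expected n_signal={self.n_signal}"
            )
        if self.n_signal > 0 and any(b < 1 for b in self.block_sizes):
            raise InvalidParameterError("block sizes must be positive")
        lo, hi = self.loading_range
        if not (0 < lo <= hi):
            raise InvalidParameterError(f"loading_range must satisfy 0 < low <= high, got {self.loading_range}")
        if not (0 < self.within_block_corr < 1):
            raise InvalidParameterError("within_block_corr must lie in (0, 1)")
        if not (0 <= self.noise_signal_mix < 1):
            raise InvalidParameterError("noise_signal_mix must lie in [0, 1)")
        if self.k_true < 0:
            raise InvalidParameterError("k_true must be >= 0")
        if not (0 < self.control_fraction <= 1):
            raise InvalidParameterError("control_fraction must lie in (0, 1]")
        if not (0 <= self.contaminate_controls < 1):
            raise InvalidParameterError("contaminate_controls must lie in [0, 1)")
        for name in ("noise_to_signal", "eps_to_signal"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if (self.sigma_alpha is not None and self.sigma_alpha <= 0) or (
            self.sigma_eps is not None and self.sigma_eps <= 0
        ):
            raise InvalidParameterError("explicit noise scales must be > 0")

    @property
    def n_blocks(self) -> int:
        return len(self.block_sizes)

    @property
    def p(self) -> int:
        """Total signal-factor count: shared block factors plus private ones."""
        return self.n_blocks + self.n_signal

    def signal_variance(self) -> float:
        """Expected per-gene variance of the signal component X beta.

        E[lambda^2]/h with lambda ~ Uniform(loading_range) and
        h = within_block_corr: the shared loading contributes E[lambda^2], the
        private loading lambda^2 (1-h)/h.
        """
        lo, hi = self.loading_range
        e_lam2 = (lo * lo + lo * hi + hi * hi) / 3.0
        return e_lam2 / self.within_block_corr

    def resolved_scales(self) -> tuple[float, float]:
        """(sigma_alpha, sigma_eps), auto-calibrated unless given explicitly.

        Calibration keeps per-gene Var(W alpha) = k_true * sigma_alpha^2 at
        noise_to_signal times the signal variance (W columns have unit
        variance for any mixing level) and Var(eps) at eps_to_signal times it.
        """
        v_sig = self.signal_variance()
        if self.sigma_alpha is not None:
            s_a = self.sigma_alpha
        else:
            s_a = float(np.sqrt(self.noise_to_signal * v_sig / max(self.k_true, 1)))
        s_e = self.sigma_eps if self.sigma_eps is not None else float(np.sqrt(self.eps_to_signal * v_sig))
        return s_a, s_e


@dataclass
class SimulationTruth:
    """The generating components and the analytic gene-gene correlation."""

    X: np.ndarray
    beta: np.ndarray
    W: np.ndarray
    alpha: np.ndarray
    eps: np.ndarray
    true_corr: np.ndarray
    design: SimulationDesign
    signal_gene_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    mixing: np.ndarray | None = None  # column-unit-norm A coupling W to shared factors

    @property
    def n_shared_factors(self) -> int:
        return self.design.n_blocks


def _draw_loadings(design: SimulationDesign, rng: np.random.Generator) -> np.ndarray:
    """beta with shared block loadings and private loadings fixing |r| = h."""
    nb, n_sig, n = design.n_blocks, design.n_signal, design.n
    h = design.within_block_corr
    lo, hi = design.loading_range
    beta = np.zeros((nb + n_sig, n))
    gi = 0
    for b, size in enumerate(design.block_sizes):
        lam = rng.uniform(lo, hi, size) * rng.choice([-1.0, 1.0], size)
        for j in range(size):
            beta[b, gi] = lam[j]
            beta[nb + gi, gi] = abs(lam[j]) * np.sqrt((1.0 - h) / h)
            gi += 1
    return beta


def generate_dataset(
    design: SimulationDesign,
) -> tuple[ExpressionMatrix, SimulationTruth, ControlGeneSet]:
    """Draw one dataset; byte-reproducible from ``design.seed``.

    Returns the expression matrix (samples x genes, log-scale by convention),
    the generating truth, and the designated negative-control set (non-signal
    genes, optionally thinned by ``control_fraction`` and contaminated with
    relabelled signal genes by ``contaminate_controls``).
    """
    rng = np.random.default_rng(design.seed)
    m, n, n_sig, nb = design.m, design.n, design.n_signal, design.n_blocks
    s_alpha, s_eps = design.resolved_scales()

    X = rng.standard_normal((m, design.p))
    beta = _draw_loadings(design, rng)

    k = design.k_true
    c = design.noise_signal_mix
    if k > 0:
        A = rng.standard_normal((nb, k)) if nb > 0 else np.zeros((0, k))
        if nb > 0:
            A /= np.linalg.norm(A, axis=0, keepdims=True)
        G = rng.standard_normal((m, k))
        shared = X[:, :nb]
        W = np.sqrt(c) * shared @ A + np.sqrt(1.0 - c) * G if nb > 0 else G
        alpha = rng.normal(0.0, s_alpha, (k, n))
    else:
        A = None
        W = np.zeros((m, 0))
        alpha = np.zeros((0, n))

    eps = rng.normal(0.0, s_eps, (m, n))
    values = X @ beta + W @ alpha + eps

    gene_ids = [f"gene_{i:04d}" for i in range(n)]
    sample_ids = [f"sample_{i:03d}" for i in range(m)]
    Y = ExpressionMatrix(values, sample_ids, gene_ids)

    signal_idx = np.arange(n_sig)
    truth = SimulationTruth(
        X=X, beta=beta, W=W, alpha=alpha, eps=eps,
        true_corr=_analytic_correlation(beta, n_sig, n),
        design=design, signal_gene_idx=signal_idx,
        mixing=A if (k > 0 and nb > 0) else None,
    )

    non_signal = np.arange(n_sig, n)
    if non_signal.size == 0:
        raise InvalidParameterError("design leaves no non-signal genes to act as negative controls")
    n_keep = max(1, int(round(design.control_fraction * non_signal.size)))
    keep = np.sort(rng.choice(non_signal, size=n_keep, replace=False))
    if design.contaminate_controls > 0 and n_sig > 0:
        n_bad = int(round(design.contaminate_controls * n_sig))
        if n_bad > 0:
            bad = np.sort(rng.choice(signal_idx, size=n_bad, replace=False))
            keep = np.sort(np.concatenate([keep, bad]))
    controls = ControlGeneSet([gene_ids[i] for i in keep], role="negative")

    if k > 0 and nb > 0:
        logger.info(
            "generated %dx%d dataset (seed=%d): realized avg |Cor(W,X_shared)| = %.4f",
            m, n, design.seed, realized_noise_signal_correlation(truth),
        )
    return Y, truth, controls


def _analytic_correlation(beta: np.ndarray, n_signal: int, n: int) -> np.ndarray:
    gram = beta.T @ beta
    d = np.sqrt(np.diag(gram)).copy()
    zero_sig = np.flatnonzero(d[:n_signal] == 0)
    if zero_sig.size:
        raise DegenerateInputError(f"signal genes with zero-norm loadings: {zero_sig[:10]}")
    d[d == 0] = 1.0  # non-signal genes: row/col of zeros, diagonal forced to 1
    corr = gram / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


def true_correlations(truth: SimulationTruth) -> CorrelationSet:
    """The analytic gene-gene correlation r = (beta'beta)_ij / sqrt(...)_ii(...)_jj.

    Valid because the factor columns of X are independent with unit variance,
    so Cov(X beta) = beta' beta. Non-signal genes are uncorrelated with
    everything; the diagonal is 1 by convention.
    """
    n = truth.design.n
    gene_ids = [f"gene_{i:04d}" for i in range(n)]
    return CorrelationSet(truth.true_corr, gene_ids, source_label="truth", m_samples=0)


def realized_noise_signal_correlation(truth: SimulationTruth) -> float:
    """Mean |Pearson r| between unwanted factors and shared signal factors.

    Averages over all (column of W, shared column of X) pairs; the per-gene
    private factors are excluded -- they are gene-specific biological
    variation, and diluting the mean over them would make the statistic
    meaningless as a measure of signal-noise confounding. Returns 0.0 (with a
    log note) when there are no unwanted factors or no shared factors.
    """
    k = truth.W.shape[1]
    nb = truth.n_shared_factors
    if k == 0 or nb == 0:
        logger.info("realized_noise_signal_correlation: empty factor set, returning 0.0")
        return 0.0
    shared = truth.X[:, :nb]
    C = np.corrcoef(truth.W.T, shared.T)[:k, k:]
    return float(np.abs(C).mean())
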