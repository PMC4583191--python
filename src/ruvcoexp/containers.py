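"""Core in-memory containers.

Expression data are held samples x genes internally (the orientation of the
linear model Y = X beta + W alpha + eps); on disk the conventional
genes-in-rows layout is used and transposed on ingestion (see :mod:`ruvcoexp.io`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError

CENTER_TOL = 1e-10


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Series(list(ids)).value_counts()
        dupes = dupes[dupes > 1].index.tolist()
        raise InvalidInputError(f"duplicate {what}: {dupes[:10]}")


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values for m samples over n genes.

    Attributes
    ----------
    values : (m, n) ndarray
        Samples in rows, genes in columns.
    sample_ids, gene_ids : list of str
        Unique identifiers for rows / columns.
    centered : bool
        True when every gene has zero mean across samples (within 1e-10).
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    centered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise InvalidInputError("values must be a 2-d array (samples x genes)")
        m, n = self.values.shape
        if m != len(self.sample_ids) or n != len(self.gene_ids):
            raise InvalidInputError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        _check_unique(self.sample_ids, "sample_ids")
        _check_unique(self.gene_ids, "gene_ids")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError(
                "expression matrix contains missing or non-finite values; "
                "impute or drop them at ingestion"
            )
        if self.centered:
            worst = float(np.abs(self.values.mean(axis=0)).max(initial=0.0))
            if worst > CENTER_TOL:
                raise InvalidInputError(
                    f"centered flag set but max |gene mean| = {worst:.3g} > {CENTER_TOL}"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_indices(self, ids: Sequence[str]) -> np.ndarray:
        """Positions of ``ids`` in gene order; unknown ids raise."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in ids if g not in lookup]
        if missing:
            raise InvalidInputError(f"genes not in matrix: {missing[:10]}")
        return np.array([lookup[g] for g in ids], dtype=int)

    def subset_genes(self, ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_indices(ids)
        return ExpressionMatrix(
            self.values[:, idx], list(self.sample_ids), [self.gene_ids[i] for i in idx],
            centered=self.centered,
        )

    def with_values(self, values: np.ndarray, centered: bool | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values, list(self.sample_ids), list(self.gene_ids),
            centered=self.centered if centered is None else centered,
        )

    def to_frame(self) -> pd.DataFrame:
        """Genes-in-rows DataFrame (the on-disk convention)."""
        return pd.DataFrame(self.values.T, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ControlGeneSet:
    """A named gene subset with a role (negative/positive/random controls)."""

    ids: list[str]
    role: str = "negative"

    ROLES = ("negative", "positive", "random")

    def __post_init__(self) -> None:
        self.ids = [str(g) for g in self.ids]
        if not self.ids:
            raise InvalidInputError("control gene set is empty")
        _check_unique(self.ids, "control ids")
        if self.role not in self.ROLES:
            raise InvalidParameterError(f"role must be one of {self.ROLES}, got {self.role!r}")

    def __len__(self) -> int:
        return len(self.ids)

    def indices_in(self, Y: ExpressionMatrix) -> np.ndarray:
        return Y.gene_indices(self.ids)


@dataclass
class RUVParams:
    """Tuning parameters of the cleaning step.

    k is the assumed dimension of the unwanted variation; nu >= 0 is the
    ridge penalty applied when regressing the centered data on the estimated
    factors (nu = 0 is ordinary least squares, large nu leaves the data
    untouched).
    """

    k: int
    nu: float = 0.0

    def __post_init__(self) -> None:
        if int(self.k) != self.k or self.k < 0:
            raise InvalidParameterError(f"k must be a non-negative integer, got {self.k}")
        self.k = int(self.k)
        if self.nu < 0:
            raise InvalidParameterError(f"nu must be >= 0, got {self.nu}")
        self.nu = float(self.nu)


@dataclass
class RUVFit:
    """Result of factor estimation and ridge regression.

    W_hat holds factor scores scaled by singular values (U_k D_k); basis is
    the orthonormal U_k kept for diagnostics and invariant checks.
    singular_values are all leading singular values of the centered
    negative-control submatrix (scree material).
    """

    W_hat: np.ndarray
    basis: np.ndarray
    singular_values: np.ndarray
    params: RUVParams
    control_ids: list[str]
    alpha_hat: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.W_hat.shape[1]

    def variance_removed(self, Ystar: ExpressionMatrix) -> float:
        """Fraction of total (centered) variance explained by W_hat alpha_hat."""
        if self.alpha_hat is None:
            raise InvalidInputError("alpha_hat not estimated yet")
        total = float(np.sum(Ystar.values ** 2))
        if total == 0:
            return 0.0
        removed = float(np.sum((self.W_hat @ self.alpha_hat) ** 2))
        return removed / total


@dataclass
class CorrelationSet:
    """A symmetric correlation matrix over a named gene subset."""

    corr: np.ndarray
    gene_ids: list[str]
    source_label: str = "raw"
    m_samples: int = 0

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        n = len(self.gene_ids)
        if self.corr.shape != (n, n):
            raise InvalidInputError(f"corr shape {self.corr.shape} != ({n}, {n})")
        _check_unique(self.gene_ids, "gene_ids")
        if n and np.abs(self.corr - self.corr.T).max() > 1e-12:
            raise InvalidInputError("correlation matrix is not symmetric within 1e-12")
        if n and np.abs(np.diag(self.corr) - 1.0).max() > 0:
            raise InvalidInputError("correlation matrix diagonal must be exactly 1")
        if n and (np.abs(self.corr) > 1.0).any():
            raise InvalidInputError("correlation entries must lie in [-1, 1]")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def offdiag_values(self) -> np.ndarray:
        """Upper-triangle correlations, each unordered pair once."""
        iu = np.triu_indices(self.n_genes, k=1)
        return self.corr[iu]

    def reordered_to(self, gene_ids: Sequence[str]) -> "CorrelationSet":
        if set(gene_ids) != set(self.gene_ids):
            raise InvalidInputError("cannot reorder: gene sets differ")
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([lookup[g] for g in gene_ids], dtype=int)
        return CorrelationSet(
            self.corr[np.ix_(idx, idx)], list(gene_ids), self.source_label, self.m_samples
        )


@dataclass
class MetricReport:
    """Accuracy of an estimated correlation matrix against the truth."""

    fn2: float
    ws_pct: float | None
    n_pairs: int
    n_nonzero_pairs: int
    clipping_count: int
    source_label: str = ""

    def to_dict(self) -> dict:
        return {
            "fn2": self.fn2,
            "ws_pct": self.ws_pct,
            "n_pairs": self.n_pairs,
            "n_nonzero_pairs": self.n_nonzero_pairs,
            "clipping_count": self.clipping_count,
            "source_label": self.source_label,
        }


@dataclass
class SampleAnnotation:
    """Per-sample covariates (batch, source, age, ...) for diagnostics."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.table, pd.DataFrame):
            self.table = pd.DataFrame(self.table)
        _check_unique([str(i) for i in self.table.index], "annotation sample ids")

    def aligned_to(self, Y: ExpressionMatrix) -> pd.DataFrame:
        missing = [s for s in Y.sample_ids if s not in self.table.index]
        if missing:
            raise InvalidInputError(f"annotation missing samples: {missing[:10]}")
        return self.table.loc[Y.sample_ids]
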