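"""Correlation estimation and accuracy metrics.

The central accuracy measure is the squared average error of Fisher
z-transformed correlation estimates over all gene pairs,

    FN^2 = 2 sum_{i<j} (arctanh(r_hat_ij) - arctanh(r_ij))^2 / (n (n - 1)),

together with the percentage of truly correlated pairs whose estimate has the
wrong sign (%WS). Correlations are clipped to |r| <= 1 - 1e-6 before arctanh;
clipped entries are counted and reported.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ControlGeneSet, CorrelationSet, ExpressionMatrix, MetricReport
from .errors import (
    GeneSetMismatchError,
    InvalidInputError,
    UndefinedMetricError,
)

logger = logging.getLogger(__name__)

ARCTANH_CLIP = 1.0 - 1e-6


def pearson_matrix(
    Y: ExpressionMatrix, genes: ControlGeneSet | Sequence[str] | None = None,
    source_label: str | None = None,
) -> CorrelationSet:
    """Pearson correlations across samples for each pair of selected genes.

    Zero-variance genes are excluded with a warning (they are flagged, not
    silently dropped downstream of cleaning). Invariant to per-gene affine
    rescaling of the input.
    """
    if Y.n_samples < 3:
        raise InvalidInputError("correlation estimation requires >= 3 samples")
    if genes is None:
        ids = list(Y.gene_ids)
    elif isinstance(genes, ControlGeneSet):
        ids = list(genes.ids)
    else:
        ids = [str(g) for g in genes]
    idx = Y.gene_indices(ids)
    vals = Y.values[:, idx]
    sd = vals.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(
            f"excluding {len(dropped)} zero-variance gene(s) from correlation: "
            f"{dropped[:5]}", stacklevel=2,
        )
        ids = [g for g, k in zip(ids, keep) if k]
        vals = vals[:, keep]
    if len(ids) == 0:
        raise InvalidInputError("no genes with nonzero variance")
    corr = np.corrcoef(vals.T)
    corr = np.atleast_2d(corr)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    label = source_label if source_label is not None else ("centered" if Y.centered else "raw")
    return CorrelationSet(corr, ids, source_label=label, m_samples=Y.n_samples)


def _aligned_pair(est: CorrelationSet, truth: CorrelationSet) -> tuple[np.ndarray, np.ndarray]:
    if set(est.gene_ids) != set(truth.gene_ids):
        raise GeneSetMismatchError(
            f"gene sets differ: {len(est.gene_ids)} estimated vs {len(truth.gene_ids)} true genes"
        )
    truth = truth.reordered_to(est.gene_ids)
    iu = np.triu_indices(est.n_genes, k=1)
    return est.corr[iu], truth.corr[iu]


def _clip_count(r: np.ndarray) -> int:
    return int(np.count_nonzero(np.abs(r) > ARCTANH_CLIP))


def fn_squared(est: CorrelationSet, truth: CorrelationSet) -> float:
    """Squared average Fisher-z error over all off-diagonal pairs."""
    r_hat, r = _aligned_pair(est, truth)
    if r.size == 0:
        raise UndefinedMetricError("FN^2 needs at least one gene pair")
    z_hat = np.arctanh(np.clip(r_hat, -ARCTANH_CLIP, ARCTANH_CLIP))
    z = np.arctanh(np.clip(r, -ARCTANH_CLIP, ARCTANH_CLIP))
    return float(np.mean((z_hat - z) ** 2))


def wrong_sign_pct(est: CorrelationSet, truth: CorrelationSet) -> float:
    """Percentage of truly correlated pairs estimated with the wrong sign.

    Pairs with true r = 0 are excluded from the denominator; an estimate of
    exactly 0 on a truly correlated pair counts as wrong.
    """
    r_hat, r = _aligned_pair(est, truth)
    nz = r != 0
    if not nz.any():
        raise UndefinedMetricError("%WS undefined: no pairs with nonzero true correlation")
    wrong = np.sign(r_hat[nz]) != np.sign(r[nz])
    return float(100.0 * np.mean(wrong))


def metric_report(est: CorrelationSet, truth: CorrelationSet) -> MetricReport:
    """FN^2 and %WS in one report; %WS is None for an all-null truth."""
    r_hat, r = _aligned_pair(est, truth)
    nz = r != 0
    ws = wrong_sign_pct(est, truth) if nz.any() else None
    return MetricReport(
        fn2=fn_squared(est, truth),
        ws_pct=ws,
        n_pairs=int(r.size),
        n_nonzero_pairs=int(nz.sum()),
        clipping_count=_clip_count(r_hat) + _clip_count(r),
        source_label=est.source_label,
    )


def correlation_pvalues(corrs: CorrelationSet) -> np.ndarray:
    """Two-sided p-values from the correlation t-test, per pair.

    t = r sqrt((m - 2) / (1 - r^2)) on m - 2 degrees of freedom; |r| is
    clipped just below 1 first. Requires the correlation set to record
    m >= 4 samples.
    """
    m = corrs.m_samples
    if m < 4:
        raise InvalidInputError(f"t-test needs m >= 4 samples, correlation set records m={m}")
    r = np.clip(corrs.corr, -ARCTANH_CLIP, ARCTANH_CLIP)
    t = r * np.sqrt((m - 2) / (1.0 - r ** 2))
    return 2.0 * stats.t.sf(np.abs(t), df=m - 2)


class AbsCorrelationECDF:
    """Right-continuous ECDF of off-diagonal |r|, evaluable at arbitrary points."""

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise InvalidInputError("ECDF of an empty correlation set")
        self.values = np.sort(values)
        self.fractions = np.arange(1, self.values.size + 1) / self.values.size

    def __call__(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        out = np.searchsorted(self.values, x, side="right") / self.values.size
        return float(out) if out.ndim == 0 else out

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"abs_corr": self.values, "cum_fraction": self.fractions})


def ecdf_abs_correlations(corrs: CorrelationSet) -> AbsCorrelationECDF:
    """ECDF of the absolute off-diagonal correlations of a gene set."""
    return AbsCorrelationECDF(np.abs(corrs.offdiag_values()))


def rank_differences(
    reference: CorrelationSet,
    cleaned: CorrelationSet,
    focus_pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Rank shifts of focus pairs between two correlation sets.

    All off-diagonal pairs of the common gene universe are ranked by |r|,
    highest first, with average ranks on ties. For each focus pair the
    difference rank_in_reference - rank_in_cleaned is reported: positive
    values mean the pair moved up (became relatively stronger) after
    cleaning.
    """
    if set(reference.gene_ids) != set(cleaned.gene_ids):
        raise GeneSetMismatchError("rank comparison requires the identical gene universe")
    cleaned = cleaned.reordered_to(reference.gene_ids)
    n = reference.n_genes
    iu = np.triu_indices(n, k=1)
    ranks_ref = stats.rankdata(-np.abs(reference.corr[iu]), method="average")
    ranks_cln = stats.rankdata(-np.abs(cleaned.corr[iu]), method="average")

    pos = {g: i for i, g in enumerate(reference.gene_ids)}
    pair_index = {}
    for flat, (i, j) in enumerate(zip(*iu)):
        pair_index[(i, j)] = flat
    rows = []
    for a, b in focus_pairs:
        if a not in pos or b not in pos or a == b:
            raise InvalidInputError(f"focus pair ({a}, {b}) not in the gene universe")
        i, j = sorted((pos[a], pos[b]))
        flat = pair_index[(i, j)]
        rows.append({
            "gene_a": a, "gene_b": b,
            "rank_reference": ranks_ref[flat],
            "rank_cleaned": ranks_cln[flat],
            "rank_difference": ranks_ref[flat] - ranks_cln[flat],
        })
    return pd.DataFrame(rows)


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (utility for the prioritizer; metrics report raw p)."""
    from statsmodels.stats.multitest import multipletests

    flat = np.asarray(pvals, dtype=float).ravel()
    adj = multipletests(flat, method="fdr_bh")[1]
    return adj.reshape(np.shape(pvals))
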