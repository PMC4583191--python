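"""Guilt-by-association candidate-gene prioritization.

A candidate is prioritized when its expression profile correlates, beyond a
null-derived threshold, with at least ``min_links`` confirmed disease genes.
The threshold is the ``null_quantile`` quantile of |r| among a random gene
set, standing in for the unknown distribution of biologically meaningless
correlations. On noise-dominated data this null distribution collapses
upward; when its median exceeds 0.5 no meaningful threshold exists and an
explicit not-computable status is returned instead of a number -- callers
must branch on it rather than catch an exception.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ControlGeneSet, ExpressionMatrix
from .errors import InvalidInputError, InvalidParameterError
from .metrics import pearson_matrix
from .controls import sample_random_genes

logger = logging.getLogger(__name__)

UNRELIABLE_NULL_MEDIAN = 0.5


@dataclass
class PrioritizationConfig:
    known_genes: ControlGeneSet
    candidates: ControlGeneSet
    null_size: int = 1000
    null_quantile: float = 0.99
    min_links: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.null_quantile < 1):
            raise InvalidParameterError("null_quantile must lie in (0, 1)")
        if self.min_links < 1:
            raise InvalidParameterError("min_links must be >= 1")
        if self.null_size < 10:
            raise InvalidParameterError("null_size must be >= 10")


@dataclass
class ThresholdResult:
    """Outcome of the null-based threshold construction."""

    status: str  # "ok" | "unreliable" | "undefined"
    value: float | None
    null_median: float | None
    null_size: int

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass
class PrioritizationResult:
    computable: bool
    threshold: ThresholdResult
    table: pd.DataFrame  # per candidate: link_count, max_abs_corr, prioritized
    config: PrioritizationConfig
    source_label: str = ""
    dropped_known: list[str] = field(default_factory=list)
    dropped_candidates: list[str] = field(default_factory=list)

    @property
    def prioritized(self) -> list[str]:
        if not self.computable:
            return []
        return self.table.index[self.table["prioritized"]].tolist()


def correlation_threshold(Y: ExpressionMatrix, config: PrioritizationConfig) -> ThresholdResult:
    """Significance threshold for |r| from a random-gene null distribution.

    For well-cleaned data at the default 0.99 quantile this approaches the
    Fisher-z normal approximation 2.58 / sqrt(m - 3). A degenerate null
    (no variable gene pairs) yields status "undefined"; a null median above
    0.5 yields "unreliable" -- the regime where shared systematic noise makes
    every pair of genes appear correlated.
    """
    size = min(config.null_size, Y.n_genes)
    null_set = sample_random_genes(Y, size=size, seed=config.seed)
    try:
        null_corr = pearson_matrix(Y, null_set, source_label="null")
    except InvalidInputError:
        return ThresholdResult("undefined", None, None, size)
    vals = np.abs(null_corr.offdiag_values())
    if vals.size < 10 or not np.isfinite(vals).all() or np.ptp(vals) == 0:
        return ThresholdResult("undefined", None, None, size)
    med = float(np.median(vals))
    if med > UNRELIABLE_NULL_MEDIAN:
        logger.warning("null |r| median %.3f > %.1f: no reliable threshold", med, UNRELIABLE_NULL_MEDIAN)
        return ThresholdResult("unreliable", None, med, size)
    return ThresholdResult("ok", float(np.quantile(vals, config.null_quantile)), med, size)


def prioritize_candidates(Y: ExpressionMatrix, config: PrioritizationConfig) -> PrioritizationResult:
    """Flag candidates correlated with >= min_links known genes beyond threshold.

    Known and candidate genes are intersected with the matrix (misses are
    dropped and recorded); the two sets must be disjoint afterwards. When the
    threshold is undefined or unreliable the result is marked not computable
    and carries an empty table.
    """
    present = set(Y.gene_ids)
    known = [g for g in config.known_genes.ids if g in present]
    dropped_known = [g for g in config.known_genes.ids if g not in present]
    cands = [g for g in config.candidates.ids if g in present]
    dropped_cands = [g for g in config.candidates.ids if g not in present]
    if dropped_known or dropped_cands:
        logger.info("dropped %d known and %d candidate genes absent from the matrix",
                    len(dropped_known), len(dropped_cands))
    if not known or not cands:
        raise InvalidInputError("no known genes or no candidates present in the matrix")
    overlap = set(known) & set(cands)
    if overlap:
        raise InvalidInputError(f"known and candidate sets overlap: {sorted(overlap)[:5]}")

    thr = correlation_threshold(Y, config)
    empty = pd.DataFrame(columns=["link_count", "max_abs_corr", "prioritized"])
    if not thr.ok:
        return PrioritizationResult(False, thr, empty, config,
                                    dropped_known=dropped_known, dropped_candidates=dropped_cands)

    ki = Y.gene_indices(known)
    ci = Y.gene_indices(cands)
    K = Y.values[:, ki]
    C = Y.values[:, ci]
    Kz = (K - K.mean(0)) / K.std(0)
    Cz = (C - C.mean(0)) / C.std(0)
    r = np.abs(Cz.T @ Kz) / Y.n_samples  # candidates x known
    links = (r > thr.value).sum(axis=1)
    table = pd.DataFrame(
        {
            "link_count": links,
            "max_abs_corr": r.max(axis=1),
            "prioritized": links >= config.min_links,
        },
        index=pd.Index(cands, name="candidate"),
    ).sort_values(["link_count", "max_abs_corr"], ascending=False)
    return PrioritizationResult(True, thr, table, config,
                                dropped_known=dropped_known, dropped_candidates=dropped_cands)


@dataclass
class ConsistencyReport:
    shared_candidates: list[str]
    prioritized_in_all: list[str]
    counts_by_min_studies: pd.Series  # index j -> # candidates prioritized in >= j studies

    @property
    def n_prioritized_in_all(self) -> int:
        return len(self.prioritized_in_all)


def consistency_report(results: list[PrioritizationResult]) -> ConsistencyReport:
    """Cross-study consistency of prioritization.

    Only candidates present (computable or not, but evaluated) in every input
    are compared; counts of candidates prioritized in >= j studies are
    reported for each j. Results marked not computable contribute no
    prioritizations but still restrict the shared-candidate universe.
    """
    if not results:
        raise InvalidInputError("no prioritization results to compare")
    universes = [set(r.config.candidates.ids) for r in results]
    shared = sorted(set.intersection(*universes))
    if not shared:
        raise InvalidInputError("no candidates shared across all results")
    hits = pd.DataFrame(
        {i: {g: g in set(r.prioritized) for g in shared} for i, r in enumerate(results)}
    )
    per_gene = hits.sum(axis=1)
    n = len(results)
    counts = pd.Series({j: int((per_gene >= j).sum()) for j in range(1, n + 1)})
    in_all = sorted(per_gene.index[per_gene == n])
    return ConsistencyReport(shared, in_all, counts)


def compare_methods(results_by_method: dict[str, list[PrioritizationResult]]) -> pd.DataFrame:
    """Side-by-side consistency table, one row per cleaning method."""
    rows = {}
    for method, results in results_by_method.items():
        rep = consistency_report(results)
        rows[method] = {
            "n_shared": len(rep.shared_candidates),
            "prioritized_in_all": rep.n_prioritized_in_all,
            **{f"in_ge_{j}": v for j, v in rep.counts_by_min_studies.items()},
        }
    return pd.DataFrame(rows).T
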