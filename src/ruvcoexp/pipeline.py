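"""End-to-end runs: configured cleaning, correlation sets, metrics, diagnostics.

A run is reproducible from its manifest: the manifest records the resolved
configuration, its hash, the seed and the package version. Stage failures are
logged and re-raised after partial outputs are preserved.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .containers import ControlGeneSet, ExpressionMatrix, RUVParams
from .comparators import background_correct, quantile_normalize
from .controls import load_gene_set, sample_random_genes
from .diagnostics import correlation_density, pvalue_histogram, rle_summary
from .errors import InvalidParameterError
from .io import read_correlations, read_expression, write_correlations, write_expression
from .metrics import correlation_pvalues, metric_report, pearson_matrix
from .prioritize import PrioritizationConfig, prioritize_candidates
from .ruv import center_genes, ruv_random_clean

logger = logging.getLogger(__name__)

METHODS = ("raw", "bc", "qn", "bc+qn", "ruv", "bc+ruv")


@dataclass
class RunConfig:
    expression: str
    out_dir: str
    method: str = "ruv"
    neg_controls: str | None = None
    positive_controls: str | None = None
    known_genes: str | None = None
    candidates: str | None = None
    truth_correlations: str | None = None
    k: int = 3
    nu: float = 0.0
    n_random_genes: int = 1000
    null_quantile: float = 0.99
    min_links: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise InvalidParameterError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.method in ("ruv", "bc+ruv") and self.neg_controls is None:
            raise InvalidParameterError(f"method {self.method!r} requires neg_controls")

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def apply_method(
    Y: ExpressionMatrix, method: str,
    controls: ControlGeneSet | None = None,
    params: RUVParams | None = None,
):
    """Apply one cleaning method; returns (cleaned matrix, fit-or-None).

    All outputs are gene-centered so correlation computations and diagnostics
    see the same convention regardless of method.
    """
    if method not in METHODS:
        raise InvalidParameterError(f"unknown method {method!r}")
    fit = None
    if method == "raw":
        out = center_genes(Y)
    elif method == "bc":
        out = center_genes(background_correct(Y))
    elif method == "qn":
        out = center_genes(quantile_normalize(Y))
    elif method == "bc+qn":
        out = center_genes(quantile_normalize(background_correct(Y)))
    else:
        base = background_correct(Y) if method == "bc+ruv" else Y
        if controls is None or params is None:
            raise InvalidParameterError(f"method {method!r} requires controls and params")
        out, fit = ruv_random_clean(base, controls, params)
    return out, fit


def run_pipeline(config: RunConfig) -> Path:
    """Execute a configured run and write all artifacts to the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": [],
    }

    def _stage(name):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        _stage("read")
        Y = read_expression(config.expression)
        controls = (
            load_gene_set(config.neg_controls, Y, role="negative")
            if config.neg_controls else None
        )
        params = RUVParams(k=config.k, nu=config.nu)

        _stage(f"clean:{config.method}")
        cleaned, fit = apply_method(Y, config.method, controls, params)
        write_expression(cleaned, out / "cleaned.tsv")
        if fit is not None:
            (out / "fit.json").write_text(json.dumps({
                "k": fit.params.k, "nu": fit.params.nu,
                "n_controls": len(fit.control_ids),
                "singular_values": fit.singular_values.tolist(),
                "variance_removed": fit.variance_removed(center_genes(Y)),
            }, indent=2))

        _stage("correlations")
        rand = sample_random_genes(cleaned, size=min(config.n_random_genes, cleaned.n_genes),
                                   seed=config.seed)
        rand_corr = pearson_matrix(cleaned, rand, source_label=config.method)
        write_correlations(rand_corr, out / "random_gene_correlations.tsv")
        if config.positive_controls:
            pos = load_gene_set(config.positive_controls, cleaned, role="positive")
            pos_corr = pearson_matrix(cleaned, pos, source_label=config.method)
            write_correlations(pos_corr, out / "positive_control_correlations.tsv")

        if config.truth_correlations:
            _stage("metrics")
            truth = read_correlations(config.truth_correlations, source_label="truth")
            est = pearson_matrix(cleaned.subset_genes(truth.gene_ids), source_label=config.method)
            report = metric_report(est, truth)
            (out / "metrics.json").write_text(json.dumps(report.to_dict(), indent=2))

        _stage("diagnostics")
        dens = correlation_density(rand_corr)
        dens.to_frame().to_csv(out / "random_gene_density.tsv", sep="\t", index=False)
        pvals = correlation_pvalues(rand_corr)
        iu = np.triu_indices(rand_corr.n_genes, k=1)
        hist = pvalue_histogram(pvals[iu])
        hist.to_frame().to_csv(out / "pvalue_histogram.tsv", sep="\t", index=False)
        rle_summary(cleaned).to_csv(out / "rle_summary.tsv", sep="\t")

        if config.known_genes and config.candidates:
            _stage("prioritize")
            known = load_gene_set(config.known_genes, cleaned, role="positive")
            cands = load_gene_set(config.candidates, cleaned, role="random")
            pconf = PrioritizationConfig(
                known_genes=known, candidates=cands,
                null_size=min(config.n_random_genes, cleaned.n_genes),
                null_quantile=config.null_quantile,
                min_links=config.min_links, seed=config.seed,
            )
            result = prioritize_candidates(cleaned, pconf)
            result.table.to_csv(out / "prioritization.tsv", sep="\t")
            (out / "prioritization.json").write_text(json.dumps({
                "computable": result.computable,
                "threshold_status": result.threshold.status,
                "threshold": result.threshold.value,
                "null_median": result.threshold.null_median,
                "n_prioritized": len(result.prioritized),
                "prioritized": result.prioritized,
            }, indent=2))
    except Exception:
        logger.exception("pipeline failed; partial outputs preserved in %s", out)
        manifest["failed"] = True
        raise
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
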