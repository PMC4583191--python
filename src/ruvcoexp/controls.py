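"""Assembly of negative/positive/random control gene sets.

Curated lists are the preferred source of negative controls (e.g. published
housekeeping-gene catalogs); the variance-based discovery below is an
optional empirical stand-in for the "fairly constant expression" heuristic
and should be treated with the caution any data-driven control choice
deserves.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ControlGeneSet, ExpressionMatrix
from .errors import InvalidInputError, InvalidParameterError

logger = logging.getLogger(__name__)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            out.append(entry)
    return out


def load_gene_set(
    path: str | Path, Y: ExpressionMatrix, role: str = "negative"
) -> ControlGeneSet:
    """Load a gene list and intersect it with the matrix's genes.

    Duplicates are removed with a warning; entries absent from the matrix are
    logged and dropped, preserving the file's order for the rest. An empty
    intersection is an error.
    """
    raw = read_gene_list(path)
    seen: dict[str, None] = {}
    dupes = []
    for g in raw:
        if g in seen:
            dupes.append(g)
        seen[g] = None
    if dupes:
        warnings.warn(f"{len(dupes)} duplicate entr(ies) in {path}: {dupes[:5]}", stacklevel=2)
    present = set(Y.gene_ids)
    kept = [g for g in seen if g in present]
    missed = [g for g in seen if g not in present]
    if missed:
        logger.info("%d of %d ids in %s not in matrix: %s", len(missed), len(seen), path, missed[:10])
    if not kept:
        raise InvalidInputError(f"no gene in {path} matches the expression matrix")
    return ControlGeneSet(kept, role=role)


def discover_negative_controls(
    Y: ExpressionMatrix,
    fraction: float = 0.1,
    exclude: Sequence[str] | None = None,
) -> tuple[ControlGeneSet, pd.Series]:
    """Empirical negative-control discovery by low variance.

    Samples are median-scaled (per-sample median subtracted) so global
    offsets do not masquerade as gene variance; genes are then ranked by
    variance across samples and the lowest ``fraction`` returned, after
    removing any genes of interest in ``exclude``. The full variance
    distribution is returned alongside for inspection.
    """
    if Y.n_genes < 50:
        raise InvalidInputError("control discovery needs at least 50 genes")
    if not (0 < fraction <= 0.5):
        raise InvalidParameterError(f"fraction must lie in (0, 0.5], got {fraction}")
    scaled = Y.values - np.median(Y.values, axis=1, keepdims=True)
    variances = pd.Series(scaled.var(axis=0, ddof=1), index=Y.gene_ids, name="variance")
    candidates = variances.drop(index=list(exclude or []), errors="ignore")
    n_pick = max(1, int(round(fraction * Y.n_genes)))
    picked = candidates.nsmallest(n_pick).index.tolist()
    return ControlGeneSet(picked, role="negative"), variances


def sample_random_genes(
    Y: ExpressionMatrix, size: int = 1000, seed: int = 0
) -> ControlGeneSet:
    """Uniform sample of genes without replacement, reproducible from seed."""
    if size < 1 or size > Y.n_genes:
        raise InvalidParameterError(f"size must lie in [1, n={Y.n_genes}], got {size}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(Y.n_genes, size=size, replace=False))
    return ControlGeneSet([Y.gene_ids[i] for i in idx], role="random")
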