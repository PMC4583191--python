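"""Delimited-text readers and writers.

On disk, expression tables follow the de-facto convention: genes in rows
(first column gene ids), samples in columns (header row). In memory the
orientation is samples x genes; every reader transposes on ingestion and
every writer transposes back.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ControlGeneSet, CorrelationSet, ExpressionMatrix
from .errors import InvalidInputError

logger = logging.getLogger(__name__)

UNLOGGED_HINT = 50.0


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_expression(path: str | Path, impute_missing: bool = False) -> ExpressionMatrix:
    """Read a genes-in-rows TSV/CSV into a samples x genes matrix.

    The delimiter is sniffed from {tab, comma}. Values are expected on a
    log-2 scale; a maximum above 50 triggers a looks-unlogged warning.
    Missing values are rejected unless ``impute_missing`` is set, in which
    case they are replaced by the gene's mean with a logged warning.
    Duplicate gene ids and non-numeric cells are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise InvalidInputError(f"duplicate gene ids in {path}: {dupes[:10]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise InvalidInputError(
            f"non-numeric cell at gene {df.index[r]!r}, sample {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    if numeric.isna().any().any():
        if not impute_missing:
            n_missing = int(numeric.isna().sum().sum())
            raise InvalidInputError(
                f"{n_missing} missing value(s) in {path}; pass impute_missing=True "
                "to fill with per-gene means"
            )
        logger.warning("imputing %d missing value(s) with per-gene means", int(numeric.isna().sum().sum()))
        numeric = numeric.apply(lambda row: row.fillna(row.mean()), axis=1)
    if np.nanmax(numeric.to_numpy()) > UNLOGGED_HINT:
        warnings.warn(
            f"values exceed {UNLOGGED_HINT}; the data look unlogged (log-2 scale expected)",
            stacklevel=2,
        )
    return ExpressionMatrix(
        numeric.to_numpy().T, [str(s) for s in numeric.columns], [str(g) for g in numeric.index]
    )


def write_expression(Y: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    Y.to_frame().to_csv(path, sep=sep, index_label="gene_id")


def write_gene_list(ids: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(ids) + "\n")


def write_correlations(corrs: CorrelationSet, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(corrs.corr, index=corrs.gene_ids, columns=corrs.gene_ids).to_csv(
        path, sep=sep, index_label="gene_id"
    )


def read_correlations(path: str | Path, source_label: str = "file") -> CorrelationSet:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    corr = df.to_numpy(dtype=float)
    corr = (corr + corr.T) / 2.0  # undo round-trip asymmetry at float precision
    np.fill_diagonal(corr, 1.0)
    return CorrelationSet(np.clip(corr, -1, 1), [str(g) for g in df.index], source_label=source_label)
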