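"""Plot-ready diagnostic computations.

Every diagnostic returns a plain table (or small dataclass of arrays) first;
rendering is a thin optional layer so that nothing downstream depends on
graphics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .containers import CorrelationSet, ExpressionMatrix, SampleAnnotation
from .errors import InvalidInputError
from .ruv import center_genes


@dataclass
class DensityTable:
    """Kernel density of off-diagonal correlations plus location summaries."""

    grid: np.ndarray
    density: np.ndarray | None  # None => too few pairs, histogram fallback only
    hist_edges: np.ndarray
    hist_density: np.ndarray
    mean: float
    median: float
    mode: float

    def to_frame(self) -> pd.DataFrame:
        if self.density is None:
            centers = 0.5 * (self.hist_edges[:-1] + self.hist_edges[1:])
            return pd.DataFrame({"grid": centers, "density": self.hist_density})
        return pd.DataFrame({"grid": self.grid, "density": self.density})


def correlation_density(
    corrs: CorrelationSet, grid: np.ndarray | None = None
) -> DensityTable:
    """Gaussian-kernel density of the off-diagonal correlations.

    Bandwidth by Silverman's rule. For a well-cleaned dataset the density of
    correlations between random genes should be roughly normal with mode
    near 0; positive controls should sit clearly in the positive domain.
    Fewer than 10 pairs fall back to a histogram-only summary.
    """
    vals = corrs.offdiag_values()
    if vals.size == 0:
        raise InvalidInputError("no gene pairs to estimate a density from")
    if grid is None:
        grid = np.linspace(-1.0, 1.0, 401)
    hist_density, hist_edges = np.histogram(vals, bins=20, range=(-1, 1), density=True)
    mean, median = float(vals.mean()), float(np.median(vals))
    if vals.size < 10 or np.ptp(vals) == 0:
        centers = 0.5 * (hist_edges[:-1] + hist_edges[1:])
        mode = float(centers[np.argmax(hist_density)]) if np.ptp(vals) else float(vals[0])
        return DensityTable(grid, None, hist_edges, hist_density, mean, median, mode)
    kde = stats.gaussian_kde(vals, bw_method="silverman")
    density = kde(grid)
    mode = float(grid[np.argmax(density)])
    return DensityTable(grid, density, hist_edges, hist_density, mean, median, mode)


@dataclass
class PValueHistogram:
    counts: np.ndarray
    edges: np.ndarray
    first_bin_count: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left": self.edges[:-1], "bin_right": self.edges[1:], "count": self.counts,
        })


def pvalue_histogram(pvals: np.ndarray) -> PValueHistogram:
    """100 equal bins on [0, 1], left-closed right-open (last bin closed).

    The first-bin count [0, 0.01) is reported separately; for uniform
    p-values it should be about 1 % of the total.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        raise InvalidInputError("no p-values to bin")
    if (p < 0).any() or (p > 1).any():
        raise InvalidInputError("p-values outside [0, 1]")
    counts, edges = np.histogram(p, bins=np.linspace(0.0, 1.0, 101))
    return PValueHistogram(counts, edges, int(counts[0]))


def rle_summary(Y: ExpressionMatrix) -> pd.DataFrame:
    """Summary-only relative log expression: per-sample median and IQR.

    Each gene is centered on its median across samples; a well-normalized
    sample then has deviations with median near 0 and stable IQR. Summaries
    replace the full per-sample boxplots, which do not scale to hundreds of
    samples.
    """
    dev = Y.values - np.median(Y.values, axis=0, keepdims=True)
    q25, med, q75 = np.percentile(dev, [25, 50, 75], axis=1)
    return pd.DataFrame(
        {"median": med, "iqr": q75 - q25}, index=pd.Index(Y.sample_ids, name="sample_id")
    )


@dataclass
class PCAProjection:
    scores: pd.DataFrame
    variance_explained: np.ndarray


def pca_projection(
    Y: ExpressionMatrix, annotation: SampleAnnotation | None = None, d: int = 2
) -> PCAProjection:
    """Sample scores on the top-d principal axes of the gene-centered matrix.

    Annotation columns, when given, are joined to the score table so samples
    can be colored by known sources of unwanted variation; residual grouping
    by such a covariate after cleaning indicates under-correction.
    """
    if d < 1 or d > min(Y.n_samples, Y.n_genes):
        raise InvalidInputError(f"d={d} outside [1, min(m, n)={min(Y.n_samples, Y.n_genes)}]")
    Yc = Y if Y.centered else center_genes(Y)
    pca = PCA(n_components=d, svd_solver="full")
    scores = pca.fit_transform(Yc.values)
    table = pd.DataFrame(
        scores, index=pd.Index(Y.sample_ids, name="sample_id"),
        columns=[f"PC{i+1}" for i in range(d)],
    )
    if annotation is not None:
        table = table.join(annotation.aligned_to(Y))
    return PCAProjection(table, pca.explained_variance_ratio_)
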