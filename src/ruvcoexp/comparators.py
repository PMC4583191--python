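"""Baseline cleaning procedures the factor-based method is benchmarked against.

Quantile normalization forces every sample to share one empirical value
distribution. The background-correction entry is a deliberately minimal
platform-free surrogate -- a per-sample additive offset removal on the log
scale -- because intensity-model background correction needs raw probe data
that simulated log-scale matrices do not have; outputs are labelled
"BC-surrogate" wherever reported.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix


def quantile_normalize(Y: ExpressionMatrix) -> ExpressionMatrix:
    """Classic quantile normalization across samples.

    Within each sample the i-th order statistic is replaced by the mean of
    the i-th order statistics over all samples; tied values within a sample
    receive the mean of the reference values they would jointly occupy.
    Idempotent, and preserves within-sample rank order up to ties.
    """
    if Y.n_samples == 1:
        warnings.warn("quantile normalization of a single sample is the identity", stacklevel=2)
        return Y.with_values(Y.values.copy())
    vals = Y.values
    reference = np.sort(vals, axis=1).mean(axis=0)
    out = np.empty_like(vals)
    for i in range(vals.shape[0]):
        row = vals[i]
        order = np.argsort(row, kind="stable")
        assigned = np.empty_like(row)
        assigned[order] = reference
        # ties: average the reference values the tied group occupies
        out[i] = pd.Series(assigned).groupby(row, sort=False).transform("mean").to_numpy()
    return Y.with_values(out, centered=False)


def background_correct(Y: ExpressionMatrix, quantile_floor: float = 0.5) -> ExpressionMatrix:
    """Per-sample additive offset removal (the BC surrogate).

    Subtracts each sample's ``quantile_floor``-level quantile, removing
    global per-sample shifts on the log scale. Exact on data whose only
    sample-level artifact is an additive offset. The default uses the median:
    a low quantile would imitate a background floor more literally, but its
    sampling variance differs strongly across samples of multi-factor noisy
    data and the induced per-sample jitter distorts correlations -- the
    opposite of the near-neutral behavior this baseline is meant to exhibit.
    """
    offsets = np.quantile(Y.values, quantile_floor, axis=1, keepdims=True)
    return Y.with_values(Y.values - offsets, centered=False)
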