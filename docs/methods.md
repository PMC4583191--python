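# Methods

## Model and cleaning procedure

Expression on the log-2 scale is modelled as `Y = Xβ + Wα + ε` with
`Y ∈ R^{m×n}` (m samples, n genes), signal factors `X ∈ R^{m×p}`, unwanted
factors `W ∈ R^{m×k}` and i.i.d. noise `ε_j ~ N(0, σ²_ε I_m)` per gene.
Neither X nor W is observed. Negative-control genes (index set c) are assumed
to satisfy `Y_c = Wα_c + ε_c`; their variation identifies the column space of
W. Because the factor of interest is unobserved, α is estimated by regressing
the full matrix on Ŵ alone, which biases α̂ whenever X and W are correlated —
some signal is then removed with the noise. The ridge penalty ν does not
remove that bias but lets the analyst control the aggressiveness of the
removal.

The procedure: (1) center each gene; (2) SVD of the centered control
submatrix, `Ŵ = U_k D_k`; (3) `α̂ = (Ŵ'Ŵ + νI_k)⁻¹ Ŵ'Y*` over **all** genes;
(4) subtract `Ŵα̂` and re-center (mathematically a no-op since Y* and the
factor columns are centered; numerically it removes float-level drift).

Gene centering replaces any intercept estimation: estimating an intercept
through the factor model can introduce spurious correlations, and the PCC
discards gene means anyway.

### Conventions and numerical choices

- **Orientation.** In memory Y is samples × genes; on disk the conventional
  genes-in-rows table is used and transposed on ingestion.
- **Factor scaling.** `Ŵ = U_k D_k` (scores scaled by singular values), so
  `Ŵ'Ŵ = D_k² ` and ν lives on the scale of squared singular values of the
  control block. `ruv_random_clean(..., relative_nu=True)` interprets ν as a
  fraction of the squared leading singular value, making "a small ridge"
  (ν = 10⁻³) transferable across datasets. The orthonormal basis U_k is kept
  for diagnostics; its orthonormality and the ridge normal equations are
  verified to 1e-8 in the test suite.
- **"+ν" means νI_k**, the only dimensionally consistent reading.
- **k and ν are user choices.** The fit stores the full control singular-value
  spectrum for scree inspection; `suggest_nu_grid` spans 0 and
  10⁻⁴…10² × D₁². Candidates are judged with the diagnostics: random-gene
  correlation density centered at 0, positive-control correlations clearly
  positive, flat summary-RLE, and PCA scores no longer grouping by known
  noise covariates.
- **Singularity.** `Ŵ'Ŵ + νI` is singular only when ν = 0 and the factor
  basis is rank deficient; this raises a dedicated error advising ν > 0.
- **Correlation metrics.** |r| is clipped to 1 − 10⁻⁶ before arctanh; clipped
  entries are counted in every metric report. The wrong-sign percentage is
  computed only over pairs whose true correlation is nonzero; an estimated 0
  on such a pair counts as wrong. Correlation p-values come from
  `t = r√((m−2)/(1−r²))` on m − 2 df, two-sided, unadjusted (a
  Benjamini–Hochberg utility exists for the prioritizer). Rank comparisons
  rank all pairs by |r| descending with average ranks on ties.
- **Degenerate genes** (zero variance) are excluded from correlation
  computations with a warning, never from cleaning.
- **Missing values** are rejected at ingestion by default; optional per-gene
  mean imputation logs a warning.

## Synthetic data

The generator draws from the model above with an explicit, seeded design;
every parameter is overridable and logged.

- **Signal.** Signal genes are partitioned into blocks. Gene j of block b
  loads on the block's shared standard-normal factor with
  `λ_j ~ ±Uniform(loading_range)` and on a private factor of its own with
  `|λ_j|√((1−h)/h)`, so the true correlation of two genes in one block is
  exactly `±h` (`within_block_corr`, default 0.35) with sign `sign(λ_i λ_j)`.
  Genes in different blocks, and all non-signal genes, are truly
  uncorrelated. A literal one-factor-per-block design without private factors
  would force |r| = 1 within blocks; the private-factor construction is what
  makes "moderate" correlation strengths (0.26–0.42) expressible, and the
  analytic truth `r_ij = (β'β)_ij/√((β'β)_ii (β'β)_jj)` remains exact because
  all factor columns are independent with unit variance.
- **Unwanted variation.** `W = √c · X_shared A + √(1−c) · G` with A a random
  column-unit-norm mixing over the shared block factors and G fresh standard
  normal: each W column has unit variance at every mixing level c, and c = 0
  gives W ⟂ X in expectation. The realized signal–noise dependence is
  reported as the mean |Pearson r| over (W column, shared factor) pairs;
  private per-gene factors are excluded from this average since diluting it
  over hundreds of gene-specific columns would destroy its meaning as a
  confounding measure.
- **Noise calibration.** `α ~ N(0, σ²_α)` with σ_α chosen (unless given
  explicitly) so per-gene `Var(Wα) = noise_to_signal × Var(Xβ)` and
  `σ_ε` so `Var(ε) = eps_to_signal × Var(Xβ)`. Defaults 12 and 0.5 place the
  raw data in the noise-dominant regime where the sign of a raw PCC for a
  truly correlated pair is close to a coin flip (~48 % wrong) — the regime
  the benchmarks target. Measured background noise (scanner floors etc.) is
  deliberately not simulated, so the offset-removal baseline is near-neutral
  by construction.
- **Controls.** Negative controls default to all non-signal genes;
  `control_fraction` thins them and `contaminate_controls` relabels a stated
  fraction of signal genes as controls to study misspecification.
- **Default scale.** m = 180, n = 500, 250 signal genes in 10 blocks of 25,
  `loading_range = (0.3, 1.0)`, k_true = 3. Benchmarks run 20–100 replicates;
  at this scale the Monte-Carlo standard error of mean FN² and %WS is far
  below the contrasts examined and a full 100-replicate study takes a few
  seconds on one core.

What the simulation does **not** emulate: probe- or platform-specific
artifacts, intensity-dependent (nonlinear) effects, heavy-tailed or
gene-dependent random noise, and correlation between ε across genes. Passing
benchmarks therefore demonstrate correctness of the estimators and the
qualitative behavior of the cleaning strategies under the linear factor
model, not performance guarantees on any particular real platform.

### Benchmark scenario choices

- **Signal–noise confounding sweep.** The unwanted factors are given the same
  dimension as the shared signal space (k_true = number of blocks = 10) so
  that mixing can drive the mean |Cor(W, X)| up to ≈ 0.23; with k ≪ p the
  Cauchy–Schwarz bound (mean over p pairs ≤ 1/√p) caps the achievable level
  well below that. Mixing levels c = {0.13, 0.35, 0.57, 0.80} realize mean
  |Cor(W, X)| ≈ {0.11, 0.16, 0.20, 0.23}. Sweeps share replicate seeds across
  levels (common random numbers) so level contrasts are paired.
- **Prioritization scenario.** Guilt-by-association assumes a random gene set
  is an essentially-null reference, so the planted-block benchmark uses a
  sparse-signal variant (50 of 500 genes in two blocks, 80 % of non-signal
  genes as controls); with half of all genes carrying signal the null
  |r| quantile is visibly contaminated and sensitivity is not interpretable.

## Baseline normalizations

Quantile normalization replaces each within-sample order statistic by the
across-sample mean of that order statistic (ties get the mean of the
reference values their group occupies); it is idempotent and equalizes all
sample distributions exactly. The background-correction stand-in removes a
per-sample additive offset on the log scale, estimated by a per-sample
quantile — the median by default. A low quantile (e.g. 0.01) imitates a
background floor more literally, but its sampling variability differs
strongly across samples of multi-factor noisy data, and the induced jitter
itself distorts correlations; the median keeps offset removal exact while
remaining neutral when no offsets exist. True intensity-model background
correction requires raw probe data and is out of scope; all reports label
this baseline "BC-surrogate".

## Prioritization rule

A candidate is prioritized when `|PCC(candidate, known_j)| > t` for at least
`min_links` (default 2) confirmed disease genes, with `t` the
`null_quantile` (default 0.99) quantile of |r| among `null_size` random
genes. On well-cleaned data `t` approaches the Fisher-z approximation
`2.58/√(m−3)` (≈ 0.19 at m = 180). When the null distribution's median
exceeds 0.5 — the signature of data whose shared noise makes every pair look
correlated — no meaningful threshold exists; the result is returned as
not-computable (an explicit status, not an exception). Cross-study
consistency counts candidates prioritized in all (or ≥ j) studies over the
shared candidate universe.

## Negative-control discovery

When no curated list (e.g. housekeeping genes) is available, a variance
heuristic can propose controls: samples are median-scaled, genes ranked by
variance, and the lowest fraction returned together with the full variance
distribution. This is reliable only when signal variance is a dominant
per-gene component; in noise-dominant data the variance contrast between
signal and non-signal genes shrinks and the discovered set becomes impure.
Curated lists are preferred; the heuristic is optional and labelled as such.

## Known limitations

- Cleaning quality degrades as Cor(W, X) grows; the ridge softens but cannot
  remove the bias, and nothing in the data reveals the confounding level.
- Sample sizes below ~100 leave too little information for factor estimation
  and stable correlation ranks; co-expression analysis there is discouraged.
- The comparator baselines are simulation-grade surrogates, not
  platform-specific preprocessing.
- The prioritization rule is a configurable threshold-and-count scheme; it
  reproduces the qualitative behavior of published guilt-by-association
  pipelines (including the no-threshold failure mode) but no specific
  published gene list.
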