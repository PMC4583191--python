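# ruvcoexp

Removal of unwanted variation for **gene–gene correlation estimation**, with
the simulation framework, accuracy metrics, baseline normalizations,
diagnostics and guilt-by-association gene prioritization needed to evaluate
it.

## The problem

Large expression studies (microarray or sequencing) carry *systematic noise*
— batch, site, platform and tissue-handling effects that act on many genes at
once and induce dependence between samples. The Pearson correlation
coefficient (PCC), the workhorse of co-expression analysis, assumes
independent samples; under shared noise it becomes badly biased. In a
noise-dominant regime nearly **half of all truly correlated gene pairs are
estimated with the wrong sign**, and standard fixes (background correction,
quantile normalization) barely help because they only remove scaling effects,
not multi-factor noise.

## The method

Log-scale expression for m samples and n genes is modelled as

```
Y = X β + W α + ε,          Y ∈ R^{m×n}
```

with `Xβ` the biological signal, `Wα` systematic noise spanning k latent
factors, and `ε ~ N(0, σ²_ε)` random noise. *Negative-control genes* — genes
assumed to carry no signal, so that `Y_c = W α_c + ε_c` — identify the noise
structure. Cleaning proceeds in four steps:

1. **Center** each gene: `Y* = (I_m − J_m/m) Y`.
2. **Estimate Ŵ** by SVD factor analysis of the centered control submatrix
   `Y*_c` (choose k from the scree of its singular values).
3. **Ridge-regress** all genes on the factors:
   `α̂ = (Ŵ'Ŵ + ν I_k)⁻¹ Ŵ' Y*`. The penalty ν ≥ 0 controls how aggressively
   noise — and, if signal and noise are correlated, signal — is removed.
4. **Subtract**: the cleaned data are `Y* − Ŵ α̂`.

Correlations computed from the cleaned matrix are scored against a known
truth with the squared average Fisher-z error over all gene pairs,

```
FN² = 2 Σ_{i<j} (arctanh r̂_ij − arctanh r_ij)² / (n(n−1)),
```

and the percentage of truly correlated pairs with the wrong estimated sign
(%WS).

## Worked example

```python
import ruvcoexp as rc

design = rc.SimulationDesign(seed=42)          # 180 samples, 500 genes,
Y, truth, controls = rc.generate_dataset(design)  # noise 12x signal
R = rc.true_correlations(truth)

raw = rc.pearson_matrix(rc.center_genes(Y))
cleaned, fit = rc.ruv_random_clean(Y, controls,
                                   rc.RUVParams(k=3, nu=1e-3), relative_nu=True)
ruv = rc.pearson_matrix(cleaned)

for est in (raw, ruv):
    rep = rc.metric_report(est, R)
    print(f"{est.source_label:>4}:  FN^2 = {rep.fn2:.4f}   %WS = {rep.ws_pct:.2f}")
```

prints

```
 raw:  FN^2 = 0.4237   %WS = 48.33
 ruv:  FN^2 = 0.0064   %WS = 0.67
```

i.e. on raw data 48 % of the truly correlated pairs have the wrong sign —
the PCC is essentially a coin flip — while after cleaning both the Fisher-z
error and the wrong-sign rate collapse by two orders of magnitude. The
`examples/` directory has one short script per capability: simulation and
cleaning, method benchmarking, parameter choice via scree/density
diagnostics, and candidate-gene prioritization.

A thin command line mirrors the library:

```bash
ruvcoexp simulate --seed 1 --out sim/
ruvcoexp clean --expr sim/expression.tsv --neg-controls sim/negative_controls.txt \
               --k 3 --nu 0.5 --out cleaned/
ruvcoexp evaluate --est cleaned/cleaned.tsv --truth sim/true_correlations.tsv \
                  --out report.json
```

Expression tables are genes-in-rows TSV/CSV (first column gene ids, header
row sample ids, log-2 scale); gene lists are plain text, one id per line.

## Documentation

`docs/methods.md` describes the model, the simulation design and its
calibration, parameter choices, numerical conventions and known limitations.
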