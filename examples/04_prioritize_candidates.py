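"""Guilt-by-association prioritization of candidate disease genes.

Plants a disease block in simulated data: 10 confirmed disease genes and 15
unlabelled members of the same co-expression block, plus 15 pure-noise
candidates. Prioritization flags candidates correlated with at least two
confirmed genes beyond a random-gene null threshold.
"""

import ruvcoexp as rc

design = rc.SimulationDesign(
    n_signal=50, block_sizes=(25, 25), control_fraction=0.8, seed=3
)
Y, truth, controls = rc.generate_dataset(design)
cleaned, _ = rc.ruv_random_clean(
    Y, controls, rc.RUVParams(k=3, nu=1e-3), relative_nu=True
)

block = Y.gene_ids[:25]
noise_genes = [g for g in Y.gene_ids[50:] if g not in set(controls.ids)][:15]
config = rc.PrioritizationConfig(
    known_genes=rc.ControlGeneSet(block[:10], role="positive"),
    candidates=rc.ControlGeneSet(block[10:] + noise_genes, role="random"),
    null_size=200, seed=0,
)

for label, data in [("raw", rc.center_genes(Y)), ("cleaned", cleaned)]:
    result = rc.prioritize_candidates(data, config)
    true_hits = sum(g in set(result.prioritized) for g in block[10:])
    false_hits = sum(g in set(result.prioritized) for g in noise_genes)
    print(f"{label:>8}: threshold={result.threshold.status:>10}", end="")
    if result.computable:
        print(f" ({result.threshold.value:.3f})  "
              f"true candidates found: {true_hits}/15   "
              f"noise candidates flagged: {false_hits}/15")
    else:
        print("  -- prioritization not computable")

# On cleaned data nearly all planted disease-block candidates are recovered
# and pure-noise candidates are (almost) never flagged; on raw data the
# noise-inflated null threshold hides the genuine links.
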