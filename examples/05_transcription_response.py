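"""Nascent-RNA side of the method: normalize a transcript count matrix,
pick depletion-responsive genes and fit the same decay model to their
synthesis time courses."""

import numpy as np
from scipy.stats import spearmanr

from divorseq.decay import DEFAULT_TIME_GRID, TimeCourse
from divorseq.simulate import simulate_rna_experiment
from divorseq.transcription import (
    differential_expression_ttest,
    fit_synthesis_batch,
    normalize_counts_median,
    select_responsive_genes,
)

sim = simulate_rna_experiment(n_down=15, n_stable=8, seed=1)
norm = normalize_counts_median(sim.counts, biotypes={})

de = differential_expression_ttest(norm, sim.sample_times)
selected = select_responsive_genes(de)
truth_down = set(sim.truth[sim.truth.responsive].gene_id)
print(f"downregulated genes  : {len(selected.down)} "
      f"(truth {len(truth_down)}, agreement "
      f"{len(selected.down & truth_down)}/{len(truth_down)})")

times = np.asarray(DEFAULT_TIME_GRID)
tcs = []
for gene in sorted(selected.down):
    cols = sorted(norm.columns, key=lambda c: (sim.sample_times[c], c))
    values = np.full((3, len(times)), np.nan)
    for c in cols:
        t = sim.sample_times[c]
        rep = int(c.split("rep")[1]) - 1
        values[rep, list(times).index(t)] = norm.loc[gene, c]
    tcs.append(TimeCourse(gene, times, values))
fits = fit_synthesis_batch(tcs)
print(f"fittable genes       : {len(fits.fits)}/{len(tcs)}")

truth = sim.truth.set_index("gene_id")
pairs = [(truth.loc[g, "rate_true"], f.koff) for g, f in fits.fits.items()]
rho = spearmanr(*zip(*pairs)).statistic
print(f"rank corr. fitted vs true decrease rate: {rho:.3f}")
# Synthesis of responsive genes decays like binding does; the fitted
# expression-decrease rates rank-order the generating rates.
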