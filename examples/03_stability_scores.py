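"""Stability scores and differential stability across cell lines.

Quantifies a simulated experiment (expression filter, median-ratio
normalization), computes per-PAS stability scores, and screens for
transcripts whose stability differs across the three cell lines by
one-way ANOVA.
"""

import numpy as np
from scipy import stats

from apastab import sim
from apastab.quantify import filter_expressed, median_ratio_normalize
from apastab.stability import stability_table

cfg = sim.SimConfig(n_genes=150, depth=100_000, seed=3)
exp = sim.simulate_experiment(cfg)

counts = filter_expressed(exp["counts"], min_reads=5)
factors, norm, rpm = median_ratio_normalize(counts, exp["samples"])
ss = stability_table(norm, exp["samples"], pseudocount=1.0)

truth = exp["truth"].loc[ss.index]
rho = stats.spearmanr(ss["SS_lineA"], np.log(truth["half_life"])).statistic
n_sig = int((ss["anova_p"] < 0.05).sum())

print(f"expressed PAS isoforms:        {len(ss)}")
print(f"Spearman(SS, log half-life):   {rho:.3f}")
print(f"differential at p<0.05 (ANOVA): {n_sig} ({n_sig/len(ss):.1%})")
print()
print("SS tracks the true half-life ranking almost perfectly at this")
print("depth.  No decay rates differ between the simulated lines here,")
print("so ANOVA hits are false positives; with only two replicates per")
print("line the small-sample test runs slightly above its nominal 5%.")
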