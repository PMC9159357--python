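"""Sequence features explaining stability, and hexamer enrichment.

Ranks per-gene sequence features by individual R^2 against a response
built from known coefficients, then recovers a planted hexamer motif
enriched in one sequence set over another.
"""

import numpy as np
import pandas as pd

from apastab.features import hexamer_enrichment, regression_rank

rng = np.random.default_rng(2)
n = 1500
gc = rng.uniform(0.3, 0.7, size=n)
u = rng.uniform(0.3, 0.7, size=n) * (1 - gc)
size = np.exp(rng.normal(6.5, 0.8, size=n))
z = lambda x: (x - x.mean()) / x.std()
response = pd.Series(0.8 * z(gc) - 0.4 * z(u) + rng.normal(0, 0.5, size=n))
feats = pd.DataFrame({"utr3_GC": gc, "utr3_U": u, "utr3_size": size})

report = regression_rank(feats, response)
print("feature ranking by individual R^2:")
print(report.round(3).to_string())
print()

bg = ["".join(rng.choice(list("ACGT"), size=80)) for _ in range(150)]
fg = [
    s[:30] + "GCGCGC" + s[36:] if i % 2 == 0 else s
    for i, s in enumerate(
        "".join(rng.choice(list("ACGT"), size=80)) for _ in range(150)
    )
]
table, pfm = hexamer_enrichment(fg, bg)
top = table.sort_values("q").head(3)
print("top enriched hexamers (fg vs bg):")
print(top[["fg_count", "bg_count", "odds_ratio", "q"]].round(4).to_string())
print()
print("GC content carries the planted positive signal and ranks first;")
print("U content is recovered with its negative sign.  The planted")
print("GCGCGC motif tops the enrichment table.")
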