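"""3'UTR secondary-structure propensity: windowed MFE and Gini index.

Scans sequences in 100-nt windows with 50-nt overlap, folds each window
with the built-in maximum-base-pairing surrogate engine (a pseudo-
energy, not kcal/mol) and takes the median; per-position probing signal
is summarized the same way with Gini indices.
"""

import numpy as np

from apastab.structure import (
    NussinovEngine, gini, median_gini, median_mfe, window_sequence,
)

engine = NussinovEngine()
rng = np.random.default_rng(1)

unstructured = "".join(rng.choice(list("AC"), size=250))  # cannot pair
hairpins = ("GGGGGGGGAAAACCCCCCCC" + "AUAU") * 10  # pairing-rich

for name, seq in (("A/C-only", unstructured), ("hairpin-rich", hairpins)):
    windows = window_sequence(seq)
    mfe = median_mfe(seq, engine)
    print(f"{name:13s} len={len(seq):4d}  windows={len(windows)}  "
          f"median MFE={mfe:+.1f}")

flat = np.ones(200)
spiky = np.zeros(200)
spiky[::20] = 5.0
print(f"flat signal   median Gini = {median_gini(flat):.3f}")
print(f"spiky signal  median Gini = {median_gini(spiky):.3f}")
print(f"hand case [0,0,0,1]  Gini = {gini([0, 0, 0, 1]):.2f}")
print()
print("More negative median MFE = more pairing potential; higher Gini =")
print("more uneven probing reactivity, i.e. likelier structure.")
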