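"""The pulse-labeling model behind the stability score.

Under constant transcription s and first-order decay k, a 1-hour 4sU
pulse splits the steady-state pool s/k into newly made (labeled) and
pre-existing (flow-through, FT) parts.  The stability score
SS = log2(FT/4sU) is a monotone readout of k.
"""

import numpy as np

from apastab import expected_fractions, implied_stability_score

for half_life in (0.5, 1.0, 4.0, 24.0):
    k = np.log(2) / half_life
    total, labeled, unlabeled = expected_fractions(1.0, k, labeling_time=1.0)
    ss = implied_stability_score(k, 1.0)
    print(
        f"half-life {half_life:5.1f} h  ->  labeled {labeled/total:.3f}, "
        f"FT {unlabeled/total:.3f}, SS = {ss:+.3f}"
    )

print()
print("A transcript with a 1-hour half-life is split 50/50 between the")
print("two pools (SS = 0); stabler transcripts keep more pre-existing")
print("RNA and score higher.  SS is strictly decreasing in k.")
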