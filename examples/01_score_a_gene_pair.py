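"""Score one gene pair and compare with the Pearson baseline.

Builds two noisy co-regulated profiles and one anti-regulated profile,
scores both pairs through the default pipeline (10 bins, spline order 3,
S1 scoring, M3 rescaling matrix) and prints the signed scores next to the
Pearson correlation.  A positive score predicts activation, a negative
score inhibition; |score| above the 0.158 threshold counts as a call.
"""

import numpy as np

from siren import pearson_sign_score, siren_score

rng = np.random.default_rng(0)
trajectory = np.linspace(-1, 1, 171)
gene_a = trajectory + rng.normal(0, 0.15, 171)
gene_b = 0.8 * trajectory + rng.normal(0, 0.15, 171)  # co-regulated with a
gene_c = -trajectory + rng.normal(0, 0.15, 171)       # anti-regulated

for name, x, y in [("A-B (co-regulated)", gene_a, gene_b),
                   ("A-C (anti-regulated)", gene_a, gene_c)]:
    s = siren_score(x, y).score
    r = pearson_sign_score(x, y)
    call = "activating" if s >= 0.158 else "inhibitory" if s <= -0.158 else "unsigned"
    print(f"{name}: score={s:+.4f} ({call}), Pearson r={r:+.4f}")

print("\nBoth measures agree on sign here; the score additionally feeds a")
print("calibrated threshold so that random pairs are never called.")
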