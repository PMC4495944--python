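"""Construct the four rescaling matrices and show their structure.

Each 10x10 matrix weights the bin-pair grid: positive where both genes are
on the same side of their median expression, negative on opposite sides,
zero in the uninformative center — 42 positive, 42 negative and 16 zero
cells.  M3 (the default) is the pure sign pattern.
"""

import numpy as np

from siren import MATRIX_IDS, build_rescaling_matrix

for mid in MATRIX_IDS:
    m = build_rescaling_matrix(mid)
    pos, neg, zero = m.cell_counts()
    print(f"{mid}: {pos} positive / {neg} negative / {zero} zero cells, "
          f"sum={m.weights.sum():+.3f}")

print("\nM3 sign pattern (rows/cols = ascending expression bins):")
m3 = build_rescaling_matrix("M3").weights.astype(int)
for row in m3:
    print(" ".join(f"{v:+d}" if v else " 0" for v in row))

m1 = build_rescaling_matrix("M1").weights
levels = np.sort(np.unique(np.abs(m1[m1 != 0])))[::-1]
print("\nM1 graded magnitude levels:", np.round(levels, 6),
      "(adjacent steps of 1/6)")
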