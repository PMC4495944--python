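"""Calibrate the signing threshold against a permutation null.

Shuffling each gene's profile independently destroys every between-gene
dependence while preserving marginals; the largest |score| seen across
many shuffled pairs is the smallest threshold at which no random pair is
signed.  With 171 samples and default settings this ceiling sits well
below the 0.158 operating point.
"""

from siren import (
    CliqueSpec,
    make_insilico_clique,
    permutation_null_threshold,
    shuffle_expression,
)

expr, _ = make_insilico_clique(CliqueSpec(n_up=60, n_down=40, seed=5))
expr = shuffle_expression(expr, seed=5)

for n_draws in (1_000, 10_000):
    tau = permutation_null_threshold(expr, n_draws=n_draws, seed=1)
    print(f"max |score| over {n_draws:>6} null pair draws: {tau:.4f}")

print("\nAny edge scoring beyond this ceiling carries real co-expression")
print("signal; the shipped default threshold 0.158 is comfortably above it.")
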