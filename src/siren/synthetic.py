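"""Synthetic benchmarks: the two-group clique network and null data.

The clique benchmark emulates an in silico GRN built from two groups of
genes with coherent within-group and opposite between-group expression:
"up" genes follow a shared monotone trajectory across samples (think
disease progression stages), "down" genes follow its negation, and every
pair of genes is wired into a complete graph whose reference signs are
known by construction — positive within a group, negative between groups.
The canonical configuration (9 up, 6 down, 171 samples) gives 105 edges,
51 positive and 54 negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import Grn

__all__ = [
    "CliqueSpec",
    "make_insilico_clique",
    "make_null_expression",
    "shuffle_expression",
]


@dataclass(frozen=True)
class CliqueSpec:
    """Parameters of the two-group clique benchmark.

    Defaults mirror the canonical benchmark: 9 up-regulated and 6
    down-regulated genes over 171 samples.  ``noise_sd`` is the standard
    deviation of additive Gaussian noise relative to the unit-amplitude
    latent trajectory; 0.25 is the default moderate-noise setting and 0
    gives noiseless, perfectly recoverable signs.  ``trajectory`` selects
    the latent shape: a monotone ramp (default) or a 4-level step function
    mimicking discrete progression stages.
    """

    n_up: int = 9
    n_down: int = 6
    n_samples: int = 171
    noise_sd: float = 0.25
    seed: int = 0
    trajectory: str = "ramp"

    def __post_init__(self) -> None:
        if self.n_up < 0 or self.n_down < 0 or self.n_up + self.n_down < 2:
            raise ValueError("need at least 2 genes in total")
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.trajectory not in ("ramp", "steps"):
            raise ValueError("trajectory must be 'ramp' or 'steps'")

    @property
    def n_edges(self) -> int:
        n = self.n_up + self.n_down
        return n * (n - 1) // 2

    @property
    def n_positive(self) -> int:
        return (
            self.n_up * (self.n_up - 1) // 2
            + self.n_down * (self.n_down - 1) // 2
        )

    @property
    def n_negative(self) -> int:
        return self.n_up * self.n_down


def _latent_trajectory(spec: CliqueSpec) -> np.ndarray:
    if spec.trajectory == "ramp":
        return np.linspace(-1.0, 1.0, spec.n_samples)
    levels = np.array([-1.0, -1.0 / 3.0, 1.0 / 3.0, 1.0])
    return levels[(np.arange(spec.n_samples) * 4) // spec.n_samples]


def make_insilico_clique(spec: CliqueSpec | None = None) -> tuple[pd.DataFrame, Grn]:
    """Generate the clique benchmark: expression matrix plus signed GRN.

    Each gene is +-trajectory scaled by a per-gene random amplitude, with
    a per-gene random baseline offset and i.i.d. Gaussian noise; all
    randomness flows from ``spec.seed``.
    """
    spec = spec or CliqueSpec()
    rng = np.random.default_rng(spec.seed)
    latent = _latent_trajectory(spec)

    genes = [f"UP{i + 1:02d}" for i in range(spec.n_up)] + [
        f"DN{i + 1:02d}" for i in range(spec.n_down)
    ]
    directions = np.array([1.0] * spec.n_up + [-1.0] * spec.n_down)
    rows = []
    for direction in directions:
        amplitude = rng.uniform(0.5, 1.5)
        offset = rng.normal(0.0, 1.0)
        noise = rng.normal(0.0, spec.noise_sd, spec.n_samples)
        rows.append(direction * amplitude * latent + offset + noise)
    expr = pd.DataFrame(
        np.vstack(rows),
        index=genes,
        columns=[f"S{j + 1:03d}" for j in range(spec.n_samples)],
    )

    edges = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            sign = 1 if directions[i] == directions[j] else -1
            edges.append((genes[i], genes[j], sign))
    grn = Grn.from_edges(edges)
    return expr, grn


def make_null_expression(
    n_genes: int, n_samples: int, seed: int | None = None
) -> pd.DataFrame:
    """i.i.d. standard-normal expression matrix (no structure at all)."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.standard_normal((n_genes, n_samples)),
        index=[f"G{i + 1:04d}" for i in range(n_genes)],
        columns=[f"S{j + 1:04d}" for j in range(n_samples)],
    )


def shuffle_expression(expr: pd.DataFrame, seed: int | None = None) -> pd.DataFrame:
    """Permute each gene's values independently across samples.

    Destroys every between-gene dependence while preserving each gene's
    marginal value multiset — the construction behind the permutation
    null.
    """
    rng = np.random.default_rng(seed)
    values = expr.to_numpy(dtype=float).copy()
    for i in range(values.shape[0]):
        values[i] = values[i, rng.permutation(values.shape[1])]
    return pd.DataFrame(values, index=expr.index, columns=expr.columns)
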