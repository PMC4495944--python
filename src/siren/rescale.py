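"""Rescaling matrices that turn co-occurrence scores into signed scores.

Information-theoretic co-occurrence metrics are blind to the *direction*
of association: joint mass concentrated where both genes are high scores
the same as mass concentrated where one is high and the other low.  The
rescaling matrix W breaks that symmetry.  Bins are indexed by ascending
expression; the bins x bins grid splits into four quadrants at the median
bin.  Quadrants where both genes sit on the same side (low-low, high-high)
carry positive weight, mixed quadrants carry negative weight, and a
central block — where neither gene deviates enough to be informative —
is zeroed.  At the canonical 10 bins this yields exactly 42 positive,
42 negative and 16 zero cells.

Four weighting schemes share this sign pattern:

* M1 — magnitudes graded additively away from the quadrant corners in
  steps of 1/6 (0.166667).
* M2 — positive cells as M1; negative cells uniformly rescaled so the
  matrix sums to zero.
* M3 — pure sign pattern, entries in {-1, 0, +1} (the shipped default).
* M4 — negative cells as M1; positive magnitudes graded by a
  multiplicative factor of (1/6)^(1/5) per step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .discretize import DiscretizationConfig

__all__ = ["RescalingMatrix", "build_rescaling_matrix", "MATRIX_IDS"]

logger = logging.getLogger(__name__)

MATRIX_IDS = ("M1", "M2", "M3", "M4")

#: additive grading step for M1: one divided by six magnitude levels
_M1_STEP = 1.0 / 6.0
#: multiplicative grading ratio for M4, chosen so five steps reach 1/6
_M4_RATIO = (1.0 / 6.0) ** (1.0 / 5.0)


@dataclass(frozen=True)
class RescalingMatrix:
    """A bins x bins weight grid with a quadrant sign structure."""

    id: str
    weights: np.ndarray

    @property
    def num_bins(self) -> int:
        return self.weights.shape[0]

    def sign_pattern(self) -> np.ndarray:
        return np.sign(self.weights).astype(int)

    def cell_counts(self) -> tuple[int, int, int]:
        """(positive, negative, zero) cell counts."""
        w = self.weights
        return int((w > 0).sum()), int((w < 0).sum()), int((w == 0).sum())

    def to_frame(self):
        import pandas as pd

        labels = [f"bin{i}" for i in range(self.num_bins)]
        return pd.DataFrame(self.weights, index=labels, columns=labels)


def _geometry(num_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Sign pattern and zero mask for a given bin count.

    Returns (sign, zero) where sign[a, b] in {-1, +1} encodes the quadrant
    and zero[a, b] marks the central zero block.  Canonical at B=10:
    quadrant split at index 5, zero block over indices 3..6.
    """
    b = num_bins
    if b == 10:
        split, margin = 5, 3
    else:
        split = b // 2
        margin = int(np.ceil(0.3 * b))
        logger.warning(
            "rescaling matrix geometry generalized to %d bins "
            "(canonical construction is 10)",
            b,
        )
    idx = np.arange(b)
    low = idx < split
    same_side = np.equal.outer(low, low)
    sign = np.where(same_side, 1, -1)
    central = (idx >= margin) & (idx <= b - 1 - margin)
    zero = np.logical_and.outer(central, central)
    return sign, zero


def _corner_stub(sign_a: int, sign_b: int, num_bins: int) -> list[tuple[int, int]]:
    """The 2-cell diagonal stub at a quadrant's grid corner.

    ``sign_a``/``sign_b`` select the corner: -1 = low index end, +1 = high.
    """
    b = num_bins
    a0 = 0 if sign_a < 0 else b - 1
    b0 = 0 if sign_b < 0 else b - 1
    da = 1 if sign_a < 0 else -1
    db = 1 if sign_b < 0 else -1
    return [(a0, b0), (a0 + da, b0 + db)]


def _corner_distance(num_bins: int, split: int) -> np.ndarray:
    """Chebyshev distance of each cell to its own quadrant's corner stub."""
    b = num_bins
    dist = np.zeros((b, b), dtype=float)
    for a in range(b):
        for c in range(b):
            sa = -1 if a < split else 1
            sc = -1 if c < split else 1
            stub = _corner_stub(sa, sc, b)
            dist[a, c] = min(
                max(abs(a - ra), abs(c - rc)) for ra, rc in stub
            )
    return dist


def build_rescaling_matrix(
    matrix_id: str,
    config: DiscretizationConfig | None = None,
) -> RescalingMatrix:
    """Construct one of the four rescaling matrices M1-M4.

    Parameters
    ----------
    matrix_id
        One of ``"M1"``, ``"M2"``, ``"M3"``, ``"M4"``.
    config
        Discretization configuration; only ``num_bins`` is used.  Defaults
        to the canonical 10 bins.
    """
    if matrix_id not in MATRIX_IDS:
        raise ValueError(
            f"unknown rescaling matrix {matrix_id!r}; expected one of {MATRIX_IDS}"
        )
    config = config or DiscretizationConfig()
    b = config.num_bins
    sign, zero = _geometry(b)
    split = 5 if b == 10 else b // 2
    dist = _corner_distance(b, split)

    additive = np.maximum(1.0 - dist * _M1_STEP, 0.0)
    multiplicative = _M4_RATIO**dist

    if matrix_id == "M3":
        mag = np.ones((b, b))
    elif matrix_id == "M1":
        mag = additive
    elif matrix_id == "M2":
        # negative cells uniformly rescaled so the matrix sums to zero
        mag = additive.copy()
        nonzero = ~zero
        pos_sum = mag[nonzero & (sign > 0)].sum()
        neg_sum = mag[nonzero & (sign < 0)].sum()
        mag[sign < 0] *= pos_sum / neg_sum
    else:  # M4
        mag = np.where(sign > 0, multiplicative, additive)

    weights = np.where(zero, 0.0, sign * mag)
    return RescalingMatrix(id=matrix_id, weights=weights)
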