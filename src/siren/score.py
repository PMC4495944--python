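"""Information-theoretic co-occurrence metrics and the signed scoring functions.

The score for a gene pair is the expected value, under the estimated joint
bin distribution p(x, y), of a rescaled co-occurrence metric
W(x, y) * CoS(x, y).  Four scoring functions are provided:

* S1 — weighted mutual information: sum p * W * PMI (default).
* S2 — expected rescaled normalized PMI: sum p * W * NPMI.
* S3 — expected value of the rescaling matrix: sum p * W.
* S4 — normalized rescaled MI (NRMI): S1 divided by -sum p * W * log p.

With W identically +1, S1 reduces to mutual information and S4 to
normalized MI.  Cells with zero joint mass contribute 0 throughout
(the standard 0 * log 0 convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .discretize import (
    DiscretizationConfig,
    JointDistribution,
    joint_distribution,
    membership_matrix,
)
from .rescale import RescalingMatrix, build_rescaling_matrix

__all__ = [
    "ScoreConfig",
    "PairScore",
    "pmi_grid",
    "npmi_grid",
    "mutual_information",
    "score_s1",
    "score_s2",
    "score_s3",
    "score_s4",
    "contribution_grid",
    "score_joint",
    "siren_score",
    "pearson_sign_score",
    "SCORING_FUNCTIONS",
]

logger = logging.getLogger(__name__)

SCORING_FUNCTIONS = ("S1", "S2", "S3", "S4")


@dataclass(frozen=True)
class ScoreConfig:
    """Scoring configuration.

    The defaults are the selected operating point: scoring function S1,
    rescaling matrix M3, 10 bins, spline order 3.  Scores scale with the
    logarithm base; the default base 10 is the one under which the
    permutation-null ceiling of the score sits at the published +-0.158
    signing threshold (see docs/methods.md).
    """

    scoring_function: str = "S1"
    rescaling_matrix_id: str = "M3"
    log_base: float = 10.0
    discretization: DiscretizationConfig = field(default_factory=DiscretizationConfig)

    def __post_init__(self) -> None:
        if self.scoring_function not in SCORING_FUNCTIONS:
            raise ValueError(
                f"unknown scoring function {self.scoring_function!r}"
            )
        if self.log_base <= 0 or self.log_base == 1:
            raise ValueError("log_base must be positive and != 1")

    def rescaling_matrix(self) -> RescalingMatrix:
        return build_rescaling_matrix(self.rescaling_matrix_id, self.discretization)


@dataclass(frozen=True)
class PairScore:
    """Score for one gene pair, optionally with per-cell contributions."""

    gene_a: str
    gene_b: str
    score: float
    metric_grid: np.ndarray | None = None


def _as_weights(w: RescalingMatrix | np.ndarray) -> np.ndarray:
    return w.weights if isinstance(w, RescalingMatrix) else np.asarray(w, dtype=float)


def pmi_grid(jd: JointDistribution, log_base: float = 10.0) -> np.ndarray:
    """Pointwise mutual information log(p(x,y) / p(x)p(y)) per cell.

    Zero-mass cells are set to 0 by convention.
    """
    denom = np.outer(jd.marginal_x, jd.marginal_y)
    with np.errstate(divide="ignore", invalid="ignore"):
        grid = np.log(jd.joint / denom) / np.log(log_base)
    grid[jd.joint == 0] = 0.0
    return grid


def npmi_grid(jd: JointDistribution, log_base: float = 10.0) -> np.ndarray:
    """Normalized PMI: pmi / -log p(x,y), with maximum 1 at perfect association.

    Zero-mass cells are 0; a cell holding all the mass (p = 1, zero
    denominator) is assigned the perfect-association limit 1.
    """
    pmi = pmi_grid(jd, log_base)
    with np.errstate(divide="ignore", invalid="ignore"):
        neg_log_p = -np.log(jd.joint) / np.log(log_base)
        grid = pmi / neg_log_p
    grid[jd.joint == 0] = 0.0
    grid[jd.joint >= 1.0] = 1.0
    return grid


def mutual_information(jd: JointDistribution, log_base: float = 10.0) -> float:
    """MI = sum p(x,y) log(p(x,y) / p(x)p(y)); non-negative."""
    return float((jd.joint * pmi_grid(jd, log_base)).sum())


def score_s1(
    jd: JointDistribution, w: RescalingMatrix | np.ndarray, log_base: float = 10.0
) -> float:
    """Weighted mutual information: sum p * W * PMI."""
    return float((jd.joint * _as_weights(w) * pmi_grid(jd, log_base)).sum())


def score_s2(
    jd: JointDistribution, w: RescalingMatrix | np.ndarray, log_base: float = 10.0
) -> float:
    """Expected rescaled normalized PMI: sum p * W * NPMI."""
    return float((jd.joint * _as_weights(w) * npmi_grid(jd, log_base)).sum())


def score_s3(jd: JointDistribution, w: RescalingMatrix | np.ndarray) -> float:
    """Expected value of the rescaling matrix: sum p * W."""
    return float((jd.joint * _as_weights(w)).sum())


def _s4_denominator(
    jd: JointDistribution, weights: np.ndarray, log_base: float
) -> float:
    with np.errstate(divide="ignore"):
        log_p = np.log(jd.joint) / np.log(log_base)
    log_p[jd.joint == 0] = 0.0
    return float(-(jd.joint * weights * log_p).sum())


def score_s4(
    jd: JointDistribution, w: RescalingMatrix | np.ndarray, log_base: float = 10.0
) -> float:
    """Normalized rescaled MI: (sum p W PMI) / (-sum p W log p).

    A zero denominator (e.g. W summing the entropy terms to zero) yields 0
    with a warning rather than a division error.
    """
    weights = _as_weights(w)
    num = float((jd.joint * weights * pmi_grid(jd, log_base)).sum())
    den = _s4_denominator(jd, weights, log_base)
    if den == 0.0:
        logger.warning("S4 denominator is zero; returning 0")
        return 0.0
    return num / den


def contribution_grid(jd: JointDistribution, config: ScoreConfig) -> np.ndarray:
    """Per-cell contributions whose sum is the pair score.

    For S1/S2/S3 this is p * W * metric per cell; for S4 the numerator
    grid divided by the (scalar) denominator, so the sum still equals the
    score.
    """
    w = config.rescaling_matrix().weights
    base = config.log_base
    fn = config.scoring_function
    if fn == "S1":
        return jd.joint * w * pmi_grid(jd, base)
    if fn == "S2":
        return jd.joint * w * npmi_grid(jd, base)
    if fn == "S3":
        return jd.joint * w
    num = jd.joint * w * pmi_grid(jd, base)
    den = _s4_denominator(jd, w, base)
    if den == 0.0:
        return np.zeros_like(num)
    return num / den


def score_joint(jd: JointDistribution, config: ScoreConfig) -> float:
    """Apply the configured scoring function to an estimated joint grid."""
    w = config.rescaling_matrix()
    fn = config.scoring_function
    if fn == "S1":
        return score_s1(jd, w, config.log_base)
    if fn == "S2":
        return score_s2(jd, w, config.log_base)
    if fn == "S3":
        return score_s3(jd, w)
    return score_s4(jd, w, config.log_base)


def siren_score(
    profile_x: np.ndarray,
    profile_y: np.ndarray,
    config: ScoreConfig | None = None,
    gene_a: str = "x",
    gene_b: str = "y",
    materialize_grid: bool = False,
) -> PairScore:
    """Full pipeline: discretize both profiles, estimate the joint, score.

    The score is symmetric in its arguments (the rescaling matrices are
    transpose-symmetric and the joint grid transposes).  Raises
    :class:`~siren.errors.DegenerateProfileError` on a constant profile.
    """
    config = config or ScoreConfig()
    mx = membership_matrix(profile_x, config.discretization, gene_a)
    my = membership_matrix(profile_y, config.discretization, gene_b)
    jd = joint_distribution(mx, my)
    grid = contribution_grid(jd, config) if materialize_grid else None
    return PairScore(
        gene_a=gene_a,
        gene_b=gene_b,
        score=score_joint(jd, config),
        metric_grid=grid,
    )


def pearson_sign_score(profile_x: np.ndarray, profile_y: np.ndarray) -> float:
    """Pearson correlation coefficient, the conventional signing baseline."""
    x = np.asarray(profile_x, dtype=float)
    y = np.asarray(profile_y, dtype=float)
    return float(np.corrcoef(x, y)[0, 1])
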