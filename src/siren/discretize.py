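"""Soft discretization of continuous expression profiles.

Each expression profile is min-max scaled onto the knot domain of an
open-uniform B-spline basis and converted into a samples x bins matrix of
fractional bin memberships (each row a partition of unity).  A pair of
membership matrices yields a bins x bins joint probability grid, the
plug-in estimate used by all downstream information-theoretic scores.

With ``spline_order=1`` the basis functions are indicator functions and the
whole pipeline reduces to conventional hard equal-width binning; higher
orders spread each sample over up to ``spline_order`` adjacent bins, which
makes the probability estimates robust to samples sitting near bin edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .errors import DegenerateProfileError, DomainError, ShapeError

__all__ = [
    "DiscretizationConfig",
    "MembershipMatrix",
    "JointDistribution",
    "scale_to_knot_domain",
    "bspline_weights",
    "membership_matrix",
    "joint_distribution",
]


@dataclass(frozen=True)
class DiscretizationConfig:
    """Binning parameters: number of bins and B-spline order.

    Parameters
    ----------
    num_bins
        Number of bins B (>= 2).  Default 10.
    spline_order
        B-spline order k, 1 <= k <= B.  Order 1 is hard binning; order 3
        (quadratic basis) is the default.
    """

    num_bins: int = 10
    spline_order: int = 3

    def __post_init__(self) -> None:
        if self.num_bins < 2:
            raise ValueError(f"num_bins must be >= 2, got {self.num_bins}")
        if not 1 <= self.spline_order <= self.num_bins:
            raise ValueError(
                f"spline_order must be in [1, num_bins], got {self.spline_order}"
            )

    @property
    def domain_length(self) -> float:
        """Length of the knot domain, B - k + 1."""
        return float(self.num_bins - self.spline_order + 1)

    def knot_vector(self) -> np.ndarray:
        """Open-uniform knot vector with k-fold repeated boundary knots.

        k copies of 0, interior knots 1, 2, ..., B-k at unit spacing, then
        k copies of B-k+1.  This is the standard construction that makes the
        B basis functions a partition of unity on [0, B-k+1].
        """
        b, k = self.num_bins, self.spline_order
        return np.concatenate(
            [np.zeros(k), np.arange(1.0, b - k + 1), np.full(k, b - k + 1.0)]
        )


@dataclass(frozen=True)
class MembershipMatrix:
    """Per-gene soft bin assignment: samples x bins weights, rows sum to 1."""

    gene_id: str
    weights: np.ndarray  # (n_samples, num_bins)

    @property
    def n_samples(self) -> int:
        return self.weights.shape[0]

    @property
    def num_bins(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class JointDistribution:
    """Joint and marginal bin probabilities for one gene pair."""

    joint: np.ndarray  # (num_bins, num_bins)
    marginal_x: np.ndarray = field(default=None)  # type: ignore[assignment]
    marginal_y: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_samples: int = 0

    def __post_init__(self) -> None:
        if self.marginal_x is None:
            object.__setattr__(self, "marginal_x", self.joint.sum(axis=1))
        if self.marginal_y is None:
            object.__setattr__(self, "marginal_y", self.joint.sum(axis=0))

    @property
    def num_bins(self) -> int:
        return self.joint.shape[0]

    def transpose(self) -> "JointDistribution":
        return JointDistribution(
            joint=self.joint.T,
            marginal_x=self.marginal_y,
            marginal_y=self.marginal_x,
            n_samples=self.n_samples,
        )


def scale_to_knot_domain(
    profile: np.ndarray, config: DiscretizationConfig
) -> np.ndarray:
    """Affine-map a profile onto [0, B - k + 1].

    min(profile) maps to 0 and max(profile) to the domain endpoint.

    Raises
    ------
    DegenerateProfileError
        If the profile is constant (zero range).
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("profile must be a 1-D array with at least 2 values")
    lo, hi = x.min(), x.max()
    if not np.isfinite(lo) or not np.isfinite(hi):
        raise ValueError("profile contains non-finite values")
    if hi == lo:
        raise DegenerateProfileError(
            "constant profile: expression range is zero, sign is undefined"
        )
    return (x - lo) / (hi - lo) * config.domain_length


def bspline_weights(z: float, config: DiscretizationConfig) -> np.ndarray:
    """Evaluate all B basis functions of order k at a scaled value z.

    The basis lives on the open-uniform knot vector of
    :meth:`DiscretizationConfig.knot_vector`; the returned weights are
    non-negative, sum to 1, and at most ``spline_order`` consecutive entries
    are non-zero.  At the right endpoint the final basis function takes
    value 1 (right-continuous boundary convention).
    """
    if not 0.0 <= z <= config.domain_length:
        raise DomainError(
            f"scaled value {z} outside knot domain [0, {config.domain_length}]"
        )
    degree = config.spline_order - 1
    row = BSpline.design_matrix(
        np.atleast_1d(float(z)), config.knot_vector(), degree
    ).toarray()[0]
    return row


def membership_matrix(
    profile: np.ndarray,
    config: DiscretizationConfig,
    gene_id: str = "",
) -> MembershipMatrix:
    """Soft-discretize a full profile into a samples x bins weight matrix."""
    z = scale_to_knot_domain(profile, config)
    degree = config.spline_order - 1
    weights = BSpline.design_matrix(z, config.knot_vector(), degree).toarray()
    return MembershipMatrix(gene_id=gene_id, weights=weights)


def joint_distribution(
    mx: MembershipMatrix, my: MembershipMatrix
) -> JointDistribution:
    """Estimate the joint bin-probability grid for a gene pair.

    joint[a, b] = (1/N) * sum_u mx[u, a] * my[u, b]; the marginals are the
    corresponding row/column sums and equal the per-gene bin frequencies.
    """
    if mx.n_samples != my.n_samples:
        raise ShapeError(
            f"sample counts differ: {mx.n_samples} vs {my.n_samples}"
        )
    n = mx.n_samples
    joint = mx.weights.T @ my.weights / n
    return JointDistribution(
        joint=joint,
        marginal_x=mx.weights.sum(axis=0) / n,
        marginal_y=my.weights.sum(axis=0) / n,
        n_samples=n,
    )
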