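"""Performance assessment: confusion counts, accuracy-retrieval curves,
permutation-null threshold selection and the fluctuation filter.

Accuracy and retrieval follow the true-number / false-number scheme:
PTP and NTN are edges correctly signed positive and negative, NFP and PFN
those signed incorrectly; accuracy = (PTP+NTN)/(PTP+NTN+NFP+PFN) over the
reference-signed edges that received a sign, and retrieval is the fraction
of all edges that received any sign.  The signing threshold is calibrated
against a permutation null: profiles are shuffled independently across
samples (destroying all dependence while preserving marginals) and the
smallest threshold excluding every null score is reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discretize import membership_matrix, joint_distribution
from .errors import DegenerateProfileError
from .network import SignedNetwork, _threshold_sign
from .score import ScoreConfig, score_joint

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "accuracy",
    "retrieval",
    "accuracy_retrieval_curve",
    "permutation_null_threshold",
    "top_fluctuation_filter",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Signed-edge confusion table.

    Edges that are unsigned, or whose reference sign is unknown, are
    counted in ``n_signed`` / ``n_total`` but not in the four cells.
    """

    ptp: int  # predicted + with reference +
    ntn: int  # predicted - with reference -
    nfp: int  # predicted + with reference -
    pfn: int  # predicted - with reference +
    n_signed: int
    n_total: int

    @property
    def tnu(self) -> int:
        return self.ptp + self.ntn

    @property
    def fnu(self) -> int:
        return self.nfp + self.pfn


def confusion_counts(sn: SignedNetwork) -> ConfusionCounts:
    """Tally PTP/NTN/NFP/PFN over reference-signed, sign-predicted edges."""
    f = sn.frame
    if len(f) == 0:
        raise ValueError("signed network has no edges")
    pred, ref = f["predicted_sign"], f["reference_sign"]
    both = (pred != 0) & (ref != 0)
    return ConfusionCounts(
        ptp=int(((pred == 1) & (ref == 1)).sum()),
        ntn=int(((pred == -1) & (ref == -1)).sum()),
        nfp=int((both & (pred == 1) & (ref == -1)).sum()),
        pfn=int((both & (pred == -1) & (ref == 1)).sum()),
        n_signed=int((pred != 0).sum()),
        n_total=len(f),
    )


def accuracy(cc: ConfusionCounts) -> float:
    """TNu / (TNu + FNu); NaN when no reference-signed edge was signed."""
    denom = cc.tnu + cc.fnu
    if denom == 0:
        return float("nan")
    return cc.tnu / denom


def retrieval(cc: ConfusionCounts) -> float:
    """Fraction of all edges that received a sign."""
    if cc.n_total == 0:
        return 0.0
    return cc.n_signed / cc.n_total


def accuracy_retrieval_curve(
    sn: SignedNetwork, thresholds: np.ndarray | None = None
) -> pd.DataFrame:
    """Accuracy and retrieval as the signing threshold sweeps [0, 1].

    Signs are recomputed from the stored scores at each threshold; the
    default sweep uses 20 evenly spaced thresholds.  Returns a DataFrame
    with columns threshold, accuracy, retrieval (accuracy NaN where no
    reference-signed edge is signed).
    """
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 20)
    f = sn.frame
    rows = []
    for tau in np.asarray(thresholds, dtype=float):
        pred = np.array([_threshold_sign(s, tau) for s in f["score"]])
        resigned = SignedNetwork(
            frame=f.assign(predicted_sign=pred), threshold=tau
        )
        cc = confusion_counts(resigned)
        rows.append((tau, accuracy(cc), retrieval(cc)))
    return pd.DataFrame(rows, columns=["threshold", "accuracy", "retrieval"])


def permutation_null_threshold(
    expr: pd.DataFrame,
    n_draws: int = 10_000,
    config: ScoreConfig | None = None,
    seed: int | None = None,
) -> float:
    """Smallest threshold at which no permutation-null pair is signed.

    For each draw, two randomly chosen genes have their profiles permuted
    independently across samples and the pair is scored; the maximum
    |score| over all draws is returned.  Membership matrices are computed
    once per gene and row-permuted per draw (a permutation of the profile
    permutes membership rows identically), which keeps 1e4+ draws cheap.
    Constant-profile genes are excluded; degenerate draws are redrawn.
    """
    config = config or ScoreConfig()
    if len(expr) < 2:
        raise ValueError("need at least 2 genes for a permutation null")
    rng = np.random.default_rng(seed)

    memberships = []
    for gene in expr.index:
        try:
            memberships.append(
                membership_matrix(
                    expr.loc[gene].to_numpy(dtype=float),
                    config.discretization,
                    str(gene),
                )
            )
        except DegenerateProfileError:
            logger.warning("excluding constant-profile gene %s from null", gene)
    if len(memberships) < 2:
        raise ValueError("fewer than 2 non-constant genes available")

    n_genes = len(memberships)
    n_samples = memberships[0].n_samples
    max_abs = 0.0
    for _ in range(n_draws):
        i, j = rng.choice(n_genes, size=2, replace=False)
        mx = memberships[i].weights[rng.permutation(n_samples)]
        my = memberships[j].weights[rng.permutation(n_samples)]
        joint = mx.T @ my / n_samples
        jd_score = score_joint(
            joint_distribution_from_grid(joint, n_samples), config
        )
        max_abs = max(max_abs, abs(jd_score))
    return max_abs


def joint_distribution_from_grid(joint: np.ndarray, n_samples: int):
    """Wrap a precomputed joint grid (marginals derived by summation)."""
    from .discretize import JointDistribution

    return JointDistribution(joint=joint, n_samples=n_samples)


def top_fluctuation_filter(
    expr: pd.DataFrame, fraction: float, statistic: str = "variance"
) -> list[str]:
    """Identifiers of the most fluctuating genes.

    Genes are ranked by the chosen statistic (``variance`` by default,
    ``cv`` for coefficient of variation) and the top ceil(fraction * n)
    are returned, ties broken by gene identifier.  Used to restrict a GRN
    to genes whose expression actually varies.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if statistic == "variance":
        stat = expr.var(axis=1, ddof=1)
    elif statistic == "cv":
        means = expr.mean(axis=1)
        stat = expr.std(axis=1, ddof=1) / means.abs()
    else:
        raise ValueError("statistic must be 'variance' or 'cv'")
    n_keep = math.ceil(fraction * len(expr))
    order = sorted(zip(-stat.to_numpy(), expr.index.astype(str)))
    return [gene for _, gene in order[:n_keep]]
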