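"""Independent reference implementations used as test oracles.

Everything here is deliberately written from first principles (explicit
recursions and loops over samples/cells) and shares no code with the
package's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def cox_de_boor_basis(z: float, num_bins: int, order: int) -> list[float]:
    """Textbook Cox-de Boor recursion on the open-uniform knot vector.

    Knots: ``order`` copies of 0, then 1, 2, ..., B-order, then ``order``
    copies of B-order+1.  Returns the value of each of the B basis
    functions of the given order at z, with the right endpoint assigned to
    the final basis function.
    """
    b, k = num_bins, order
    t = [0.0] * k + [float(j) for j in range(1, b - k + 1)] + [float(b - k + 1)] * k
    n_knots = len(t)
    right_end = t[-1]

    # order-1 (piecewise-constant) bases: indicator of [t_i, t_{i+1})
    basis = []
    for i in range(n_knots - 1):
        if t[i] <= z < t[i + 1]:
            val = 1.0
        elif z == right_end and t[i] < t[i + 1] and t[i + 1] == right_end:
            val = 1.0  # closed right endpoint
        else:
            val = 0.0
        basis.append(val)

    for d in range(2, k + 1):  # build order d from order d-1
        nxt = []
        for i in range(len(basis) - 1):
            left = 0.0
            if t[i + d - 1] != t[i]:
                left = (z - t[i]) / (t[i + d - 1] - t[i]) * basis[i]
            right = 0.0
            if t[i + d] != t[i + 1]:
                right = (t[i + d] - z) / (t[i + d] - t[i + 1]) * basis[i + 1]
            nxt.append(left + right)
        basis = nxt
    return basis[:b]


def hard_bin_joint(x, y, num_bins: int):
    """Plug-in joint/marginal estimate from equal-width hard binning.

    Independent of the package: bins each profile with a plain
    floor((v - min) / width) rule (max value into the last bin) and counts
    co-occurrences sample by sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)

    def assign(v):
        lo, hi = v.min(), v.max()
        width = (hi - lo) / num_bins
        idx = np.minimum(((v - lo) / width).astype(int), num_bins - 1)
        return idx

    bx, by = assign(x), assign(y)
    joint = np.zeros((num_bins, num_bins))
    for a, b in zip(bx, by):
        joint[a, b] += 1.0 / n
    return joint, joint.sum(axis=1), joint.sum(axis=0)


def brute_force_joint(wx, wy):
    """Direct per-sample summation of membership-weight products."""
    wx = np.asarray(wx)
    wy = np.asarray(wy)
    n, bx = wx.shape
    by = wy.shape[1]
    joint = np.zeros((bx, by))
    for u in range(n):
        for a in range(bx):
            for b in range(by):
                joint[a, b] += wx[u, a] * wy[u, b]
    return joint / n


def brute_force_scores(joint, w, base):
    """Loop-based S1..S4 from a joint grid and weight matrix."""
    joint = np.asarray(joint)
    w = np.asarray(w)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    s1 = s2 = s3 = num4 = den4 = 0.0
    for a in range(joint.shape[0]):
        for b in range(joint.shape[1]):
            p = joint[a, b]
            s3 += p * w[a, b]
            if p == 0:
                continue
            pmi = math.log(p / (px[a] * py[b]), base)
            npmi = 1.0 if p >= 1.0 else pmi / (-math.log(p, base))
            s1 += p * w[a, b] * pmi
            s2 += p * w[a, b] * npmi
            num4 += p * w[a, b] * pmi
            den4 -= p * w[a, b] * math.log(p, base)
    s4 = 0.0 if den4 == 0 else num4 / den4
    return s1, s2, s3, s4
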