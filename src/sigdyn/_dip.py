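"""Hartigan's dip statistic of unimodality.

The dip of a distribution function F is the smallest sup-norm distance
between F and the class of unimodal distribution functions. For an
empirical CDF it is computed with the iterative greatest-convex-minorant /
least-concave-majorant squeeze of Hartigan & Hartigan: the candidate modal
interval is shrunk to where the convex and concave fits are furthest apart,
while accumulating the deviations the fits force in the discarded tails.
All internal bookkeeping is in count units (ECDF jumps of 1); the final
statistic divides by 2n.
"""

from __future__ import annotations

import numpy as np


def _gcm_chain(x: np.ndarray) -> np.ndarray:
    """mn[j] = predecessor of j on the greatest convex minorant of (x_i, i)."""
    n = len(x)
    mn = np.zeros(n, dtype=np.int64)
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            if mnj == 0:
                break
            mnmnj = mn[mnj]
            if (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    return mn


def _lcm_chain(x: np.ndarray) -> np.ndarray:
    """mj[k] = successor of k on the least concave majorant of (x_i, i)."""
    n = len(x)
    mj = np.zeros(n, dtype=np.int64)
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            if mjk == n - 1:
                break
            mjmjk = mj[mjk]
            if (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk
    return mj


def _interp(xq: float, x0: float, y0: float, x1: float, y1: float) -> float:
    if x1 == x0:
        return max(y0, y1)
    return y0 + (xq - x0) * (y1 - y0) / (x1 - x0)


def dip_statistic(values) -> float:
    """Dip statistic of a 1-D sample (sup-distance to nearest unimodal CDF).

    Ties are allowed; a constant sample has dip 0. The minimum attainable
    value for n distinct points is 1/(2n).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 2 or x[0] == x[-1]:
        return 0.0

    mn = _gcm_chain(x)
    mj = _lcm_chain(x)

    low, high = 0, n - 1
    d_count = 1.0  # running dip in count units

    while True:
        # gcm touch points on [low, high], descending; lcm ascending.
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(int(mn[gcm[-1]]))
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(int(mj[lcm[-1]]))
        gcm_asc = gcm[::-1]

        # Max gap between the concave majorant curve (heights j+1) and the
        # convex minorant curve (heights i), over [x_low, x_high].
        d = 0.0
        new_low, new_high = low, high
        # gaps at gcm touch points against the lcm curve
        li = 0
        for i in gcm_asc:
            while li + 1 < len(lcm) and lcm[li + 1] <= i:
                li += 1
            if lcm[li] == i:
                lcm_val = i + 1.0
            else:
                j0, j1 = lcm[li], lcm[min(li + 1, len(lcm) - 1)]
                lcm_val = _interp(x[i], x[j0], j0 + 1.0, x[j1], j1 + 1.0)
            gap = lcm_val - i
            if gap > d:
                d = gap
                new_low = i
                # first lcm touch point at or right of x_i
                new_high = lcm[li] if lcm[li] >= i else lcm[min(li + 1, len(lcm) - 1)]
        # gaps at lcm touch points against the gcm curve
        gi = 0
        for j in lcm:
            while gi + 1 < len(gcm_asc) and gcm_asc[gi + 1] <= j:
                gi += 1
            if gcm_asc[gi] == j:
                gcm_val = float(j)
            else:
                i0 = gcm_asc[gi]
                i1 = gcm_asc[min(gi + 1, len(gcm_asc) - 1)]
                gcm_val = _interp(x[j], x[i0], float(i0), x[i1], float(i1))
            gap = (j + 1.0) - gcm_val
            if gap > d:
                d = gap
                new_high = j
                # last gcm touch point at or left of x_j
                new_low = gcm_asc[gi] if gcm_asc[gi] <= j else gcm_asc[max(gi - 1, 0)]

        if d <= d_count:
            break

        # Deviations of the ECDF from the fits over the discarded tails.
        dip_l = 0.0
        for a, b in zip(gcm_asc, gcm_asc[1:]):
            if b > new_low:
                break
            if b - a > 1 and x[b] != x[a]:
                slope = (b - a) / (x[b] - x[a])
                for jj in range(a, b + 1):
                    t = (jj - a + 1) - (x[jj] - x[a]) * slope
                    if t > dip_l:
                        dip_l = t
        dip_u = 0.0
        for a, b in zip(lcm, lcm[1:]):
            if a < new_high:
                continue
            if b - a > 1 and x[b] != x[a]:
                slope = (b - a) / (x[b] - x[a])
                for jj in range(a, b + 1):
                    t = (x[jj] - x[a]) * slope - (jj - a - 1)
                    if t > dip_u:
                        dip_u = t
        d_count = max(d_count, dip_l, dip_u)

        if (new_low, new_high) == (low, high):
            d_count = max(d_count, d / 2.0)
            break
        low, high = new_low, new_high

    return d_count / (2.0 * n)
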