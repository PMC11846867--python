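"""Hartigan & Hartigan dip statistic.

Direct port of the classic greatest-convex-minorant / least-concave-majorant
algorithm operating on the sorted sample.  Arrays are kept 1-based internally
to mirror the original published routine.  The statistic satisfies
``dip >= 1/(2n)`` for every sample (equality for perfectly "linear" samples
such as a uniform grid).
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic"]


def dip_statistic(x) -> float:
    """Maximum distance between the empirical CDF and the closest unimodal CDF."""
    x = np.sort(np.asarray(x, dtype=float).ravel())
    n = x.size
    if n < 1:
        raise ValueError("empty sample")
    dip_min = 1.0 / (2.0 * n)
    if n < 2 or x[0] == x[-1]:
        return dip_min

    xs = np.empty(n + 1)
    xs[1:] = x
    mn = np.zeros(n + 1, dtype=np.int64)
    mj = np.zeros(n + 1, dtype=np.int64)
    gcm = np.zeros(n + 2, dtype=np.int64)
    lcm = np.zeros(n + 2, dtype=np.int64)

    # greatest convex minorant candidate predecessors
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (xs[j] - xs[mnj]) * (mnj - mnmnj) < (
                xs[mnj] - xs[mnmnj]
            ) * (j - mnj):
                break
            mn[j] = mnmnj
    # least concave majorant candidate successors
    mj[n] = n
    for j in range(n - 1, 0, -1):
        mj[j] = j + 1
        while True:
            mjj = mj[j]
            mjmjj = mj[mjj]
            if mjj == n or (xs[j] - xs[mjj]) * (mjj - mjmjj) < (
                xs[mjj] - xs[mjmjj]
            ) * (j - mjj):
                break
            mj[j] = mjmjj

    low, high = 1, n
    dip_val = 2.0 * dip_min  # the loop works with twice the dip
    while True:
        # change points of the GCM (decreasing) and LCM (increasing) on [low, high]
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        ig = l_gcm = i
        ix = ig - 1

        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        ih = l_lcm = i
        iv = 2

        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # next point is on the LCM
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) / n - (xs[lcmiv] - xs[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (n * (xs[gcmix] - xs[gcmi1]))
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # next point is on the GCM
                    lcmiv1 = lcm[iv - 1]
                    dx = (xs[gcmix] - xs[lcmiv1]) * (lcmiv - lcmiv1) / (
                        n * (xs[lcmiv] - xs[lcmiv1])
                    ) - (gcmix - lcmiv1 - 1) / n
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0 / n
        if d < dip_val:
            break

        # maximum deviation of the empirical CDF from the GCM on [low, gcm[ig]]
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0 / n
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and xs[je] != xs[jb]:
                C = (je - jb) / (n * (xs[je] - xs[jb]))
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) / n - (xs[jj] - xs[jb]) * C
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        # maximum deviation from the LCM on [lcm[ih], high]
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0 / n
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and xs[je] != xs[jb]:
                C = (je - jb) / (n * (xs[je] - xs[jb]))
                for jj in range(jb, je + 1):
                    t = (xs[jj] - xs[jb]) * C - (jj - jb - 1) / n
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dip_new = max(dip_l, dip_u)
        if dip_val < dip_new:
            dip_val = dip_new
        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]
    return float(dip_val) / 2.0
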