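"""Hartigan's dip statistic for unimodality.

The dip of a sample is the smallest sup-norm distance between its
empirical CDF and the class of unimodal distribution functions; large
values indicate multimodality.  The computation follows the classical
iterative greatest-convex-minorant / least-concave-majorant algorithm
on the sorted sample.  P-values come from Monte-Carlo calibration
against the uniform null of the same sample size (the least favorable
unimodal distribution), with an add-one correction.

The inner loop is numba-jitted; computing the dip of B null replicates
of a few thousand points takes well under a second.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["dip_statistic", "dip_test"]


@njit(cache=False)
def _dip(x: np.ndarray) -> float:
    """Dip statistic of a sorted 1-D sample (0-based port of AS 217)."""
    n = x.shape[0]
    if n < 2:
        return 0.0
    if x[n - 1] == x[0]:
        return 0.0
    low = 0
    high = n - 1
    dip = 1.0  # in units of counts/2; final value is dip / (2n) -> min 1/(2n)

    mn = np.empty(n, dtype=np.int64)
    mj = np.empty(n, dtype=np.int64)
    gcm = np.empty(n, dtype=np.int64)
    lcm = np.empty(n, dtype=np.int64)

    while True:
        # greatest convex minorant touch indices on [low, high]
        mn[low] = low
        for j in range(low + 1, high + 1):
            mn[j] = j - 1
            while True:
                mnj = mn[j]
                if mnj == low:
                    break
                mnmnj = mn[mnj]
                if (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                    break
                mn[j] = mnmnj
        # least concave majorant touch indices on [low, high]
        mj[high] = high
        for j in range(high - 1, low - 1, -1):
            mj[j] = j + 1
            while True:
                mjj = mj[j]
                if mjj == high:
                    break
                mjmjj = mj[mjj]
                if (x[j] - x[mjj]) * (mjj - mjmjj) < (x[mjj] - x[mjmjj]) * (j - mjj):
                    break
                mj[j] = mjmjj

        # collect gcm points from high down to low, lcm from low up to high
        ic = 0
        gcm[0] = high
        while gcm[ic] > low:
            gcm[ic + 1] = mn[gcm[ic]]
            ic += 1
        l_gcm = ic + 1
        ig = l_gcm

        ic = 0
        lcm[0] = low
        while lcm[ic] < high:
            lcm[ic + 1] = mj[lcm[ic]]
            ic += 1
        l_lcm = ic + 1
        ih = l_lcm

        # interval reduced to a bare pair: no structure left to find
        if l_gcm == 2 and l_lcm == 2:
            break

        # largest distance between the gcm and the lcm
        ix = l_gcm - 2
        iv = 1
        d = 0.0
        if True:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        x[lcmiv] - x[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx > d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 0:
                    ix = 0
                if iv > l_lcm - 1:
                    iv = l_lcm - 1
                if gcm[ix] == lcm[iv]:
                    break

        if d <= dip:
            break

        # dip within the current convex-minorant fit
        dip_l = 0.0
        for j in range(ig, l_gcm - 1):
            jb = gcm[j + 1]
            je = gcm[j]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if t > max_t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        # dip within the current concave-majorant fit
        dip_u = 0.0
        for j in range(ih, l_lcm - 1):
            jb = lcm[j]
            je = lcm[j + 1]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if t > max_t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = dip_l if dip_l > dip_u else dip_u
        if dip < dipnew:
            dip = dipnew
        low = gcm[ig]
        high = lcm[ih]
        if low == high:
            break

    return dip / (2.0 * n)


def dip_statistic(values: np.ndarray) -> float:
    """Dip statistic of a 1-D sample (sorted internally)."""
    x = np.sort(np.asarray(values, dtype=float))
    if x.size < 4:
        raise ValueError("dip statistic needs at least 4 observations")
    return float(_dip(x))


def dip_test(
    values: np.ndarray, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Dip statistic and Monte-Carlo p-value under the uniform null.

    ``n_boot`` uniform samples of the same size are drawn and
    p = (1 + #{D_boot >= D}) / (n_boot + 1).
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size < 4:
        raise ValueError("dip test needs at least 4 observations")
    d = float(_dip(x))
    rng = np.random.default_rng(seed)
    count = 0
    n = x.size
    for _ in range(int(n_boot)):
        u = np.sort(rng.random(n))
        if _dip(u) >= d:
            count += 1
    p = (1.0 + count) / (n_boot + 1.0)
    return d, p
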