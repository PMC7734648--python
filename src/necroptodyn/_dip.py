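"""Hartigan & Hartigan's dip statistic.

The dip of a distribution function F is the smallest sup-norm distance
between F and the class of unimodal distribution functions.  For a sample it
is computed from the empirical CDF via the greatest convex minorant (GCM) /
least concave majorant (LCM) construction: the algorithm repeatedly narrows
a candidate modal interval [x_low, x_high], measuring on the left flank how
far the empirical CDF rises above its convex minorant and on the right flank
how far it falls below its concave majorant.

The implementation below works on the sorted sample with counts as ordinates
(deviation units of 1/n are applied at the end, together with the factor 1/2
that converts a one-sided band width into a sup-norm distance).  It is
validated in the test-suite against a linear-programming oracle that
minimises the sup distance over piecewise-linear unimodal CDFs directly.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _dip_sorted(x: np.ndarray) -> float:
    """Dip statistic of an ascending-sorted 1-D array."""
    n = x.shape[0]
    if n < 2 or x[n - 1] == x[0]:
        return 0.0

    # mn[j]: previous touch index of the greatest convex minorant through
    # the points (x[i], i); mj[j]: analogous for the least concave majorant.
    mn = np.zeros(n, dtype=np.int64)
    mj = np.zeros(n, dtype=np.int64)
    mn[0] = 0
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

    gcm = np.zeros(n + 1, dtype=np.int64)
    lcm = np.zeros(n + 1, dtype=np.int64)
    low = 0
    high = n - 1
    dip = 1.0  # in count units; final value divided by 2n

    while True:
        # GCM change points on [low, high], collected from high down to low.
        gcm[0] = high
        l_gcm = 1
        while gcm[l_gcm - 1] > low:
            gcm[l_gcm] = mn[gcm[l_gcm - 1]]
            l_gcm += 1
        ig = l_gcm - 1
        ix = l_gcm - 2  # 0-based counter into gcm

        # LCM change points on [low, high], from low up to high.
        lcm[0] = low
        l_lcm = 1
        while lcm[l_lcm - 1] < high:
            lcm[l_lcm] = mj[lcm[l_lcm - 1]]
            l_lcm += 1
        ih = l_lcm - 1
        iv = 1  # 0-based counter into lcm

        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcm_ix = gcm[ix]
                lcm_iv = lcm[iv]
                if gcm_ix > lcm_iv:
                    # Next point along the merged walk comes from the LCM.
                    gcm_ix1 = gcm[ix + 1]
                    dx = (lcm_iv - gcm_ix1 + 1) - (x[lcm_iv] - x[gcm_ix1]) * (
                        gcm_ix - gcm_ix1
                    ) / (x[gcm_ix] - x[gcm_ix1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    lcm_iv1 = lcm[iv - 1]
                    dx = (x[gcm_ix] - x[lcm_iv1]) * (lcm_iv - lcm_iv1) / (
                        x[lcm_iv] - x[lcm_iv1]
                    ) - (gcm_ix - lcm_iv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 0:
                    ix = 0
                if iv > l_lcm - 1:
                    iv = l_lcm - 1
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d < dip:
            break

        # Largest rise of the ECDF above the GCM on the left flank.
        dip_l = 0.0
        for j in range(ig, l_gcm - 1):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        # Largest drop of the ECDF below the LCM on the right flank.
        dip_u = 0.0
        for j in range(ih, l_lcm - 1):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = dip_l if dip_l > dip_u else dip_u
        if dip < dipnew:
            dip = dipnew
        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2.0 * n)


def dip_statistic(sample) -> float:
    """Dip statistic of a 1-D sample (any order; ties allowed)."""
    x = np.asarray(sample, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("dip statistic requires a non-empty sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip statistic requires finite values")
    return float(_dip_sorted(np.sort(x)))
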