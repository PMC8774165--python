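"""Hartigan's dip statistic for unimodality.

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and any unimodal distribution function (convex below the mode, concave
above it, with an atom allowed only at the mode).  We compute it by binary
search on that distance ``d``: for fixed ``d`` the empirical CDF induces a
band of vertical boxes at the unique sample values, and a unimodal CDF within
the band exists iff (a) a nondecreasing convex function threads the boxes
left of some mode, (b) a nondecreasing concave function threads the boxes
right of it, and (c) the convex piece can end no higher than the concave
piece starts (the mode atom absorbs any upward jump).

Box derivation: with unique values v_1 < ... < v_m, cumulative counts c_t and
sample size n, the band |G - F_n| <= d on [v_t, v_{t+1}) pins
G(v_t) in [c_t/n - d, c_{t-1}/n + d].  Convex feasibility through boxes is
equivalent to the greatest convex minorant of the upper bounds staying above
the lower bounds; tails are anchored at 0 (far left) and 1 (far right).

p-values are Monte-Carlo calibrated against the uniform null (the standard
reference distribution for the dip), with a cached null table per sample
size so repeated tests at one cohort size cost a single calibration.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numba import njit

_ANCHOR_FACTOR = 1e7


@njit(cache=True)
def _left_scan(x, lo, hi, anchor_span):  # pragma: no cover - numba
    """Max mode index t such that a convex nondecreasing path exists through
    boxes 0..t-1 with the upper bound respected at t, anchored at 0 far left.

    Also returns, for each t, the minimum attainable path value at t (lower
    bound via chord-slope extrapolation from earlier boxes).
    """
    m = x.size
    # hull of (x, hi) points, anchored at (x[0]-anchor_span, 0)
    hx = np.empty(m + 1)
    hy = np.empty(m + 1)
    hidx = np.empty(m + 1, np.int64)
    hx[0] = x[0] - anchor_span
    hy[0] = 0.0
    hidx[0] = -1
    size = 1
    tmax = m - 1
    eps = 1e-12
    for t in range(m):
        # pop while adding (x[t], hi[t]) keeps the lower hull convex
        while size >= 2:
            x1, y1 = hx[size - 2], hy[size - 2]
            x2, y2 = hx[size - 1], hy[size - 1]
            if (y2 - y1) * (x[t] - x1) >= (hi[t] - y1) * (x2 - x1) - eps:
                size -= 1
            else:
                break
        # new last segment runs from vertex size-1 to t; hull values for
        # points strictly inside that span have dropped: recheck their lo
        j0 = hidx[size - 1] + 1
        x1, y1 = hx[size - 1], hy[size - 1]
        ok = True
        for k in range(j0, t):
            val = y1 + (hi[t] - y1) * (x[k] - x1) / (x[t] - x1)
            if val < lo[k] - 1e-9:
                ok = False
                break
        if not ok:
            tmax = t - 1
            break
        hx[size] = x[t]
        hy[size] = hi[t]
        hidx[size] = t
        size += 1
        # an empty box at t caps later modes (they need the full box here)
        if hi[t] < lo[t] - 1e-9:
            tmax = t
            break
    return tmax


@njit(cache=True)
def _min_end_values(x, lo, hi, tmax, anchor_span):  # pragma: no cover - numba
    """For each mode t <= tmax, the smallest value a convex nondecreasing
    in-band path can take at x[t], from chord-slope extrapolation."""
    m = x.size
    mins = np.zeros(m)
    if tmax < 0:
        return mins
    # s[k]: minimum outgoing slope forced at point k
    s = np.zeros(m)
    for k in range(tmax + 1):
        best = (lo[k] - 0.0) / (x[k] - (x[0] - anchor_span))
        for j in range(k):
            sl = (lo[k] - hi[j]) / (x[k] - x[j])
            if sl > best:
                best = sl
        s[k] = best if best > 0.0 else 0.0
    for t in range(tmax + 1):
        mv = 0.0
        for k in range(t):
            b = lo[k] + s[k] * (x[t] - x[k])
            if b > mv:
                mv = b
        mins[t] = mv
    return mins


@njit(cache=True)
def _feasible(x, cum, n, d, anchor_span):  # pragma: no cover - numba
    m = x.size
    lo = np.empty(m)
    hi = np.empty(m)
    for t in range(m):
        lo[t] = cum[t] / n - d
        hi[t] = (cum[t - 1] / n if t > 0 else 0.0) + d
    tmax_left = _left_scan(x, lo, hi, anchor_span)
    if tmax_left < 0:
        return False
    # reflected problem: x -> -x reversed, G -> 1 - G
    xr = np.empty(m)
    lor = np.empty(m)
    hir = np.empty(m)
    for i in range(m):
        xr[i] = -x[m - 1 - i]
        lor[i] = 1.0 - hi[m - 1 - i]
        hir[i] = 1.0 - lo[m - 1 - i]
    tmax_right_r = _left_scan(xr, lor, hir, anchor_span)
    if tmax_right_r < 0:
        return False
    tmin_right = m - 1 - tmax_right_r
    if tmin_right > tmax_left:
        return False
    mins_left = _min_end_values(x, lo, hi, tmax_left, anchor_span)
    mins_r = _min_end_values(xr, lor, hir, tmax_right_r, anchor_span)
    for t in range(tmin_right, tmax_left + 1):
        max_start_right = 1.0 - mins_r[m - 1 - t]
        if mins_left[t] <= max_start_right + 1e-12:
            return True
    return False


def dip_statistic(values) -> float:
    """Hartigan's dip statistic of a 1-d sample.

    Returns 0.0 for samples with a single unique value (a point mass is
    unimodal); the minimum for an all-distinct sample is 1/(2n).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("dip_statistic expects a 1-d sample")
    if x.size == 0:
        raise ValueError("dip_statistic expects a non-empty sample")
    if np.any(~np.isfinite(x)):
        raise ValueError("dip_statistic: sample contains non-finite values")
    n = x.size
    uniq, counts = np.unique(x, return_counts=True)
    if uniq.size == 1:
        return 0.0
    cum = np.cumsum(counts).astype(float)
    span = uniq[-1] - uniq[0]
    anchor_span = span * _ANCHOR_FACTOR
    lo_d, hi_d = 0.0, 0.25
    # the dip is scale-free in the ordinates; 1e-9 resolution is far below
    # any Monte-Carlo discrimination at usable sample sizes
    while hi_d - lo_d > 1e-9:
        mid = 0.5 * (lo_d + hi_d)
        if _feasible(uniq, cum, float(n), mid, anchor_span):
            hi_d = mid
        else:
            lo_d = mid
    return hi_d


@lru_cache(maxsize=32)
def _null_dips(n: int, n_boot: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return np.array([dip_statistic(rng.random(n)) for _ in range(n_boot)])


def dip_test(values, n_boot: int = 2000, seed: int = 0) -> tuple[float, float]:
    """Dip statistic and Monte-Carlo p-value against the uniform null.

    p = (1 + #{null dips >= observed}) / (n_boot + 1).  The null table is
    drawn once per (sample size, n_boot, seed) and cached.
    """
    x = np.asarray(values, dtype=float)
    d = dip_statistic(x)
    null = _null_dips(int(x.size), int(n_boot), int(seed))
    p = (1.0 + float(np.sum(null >= d - 1e-12))) / (n_boot + 1.0)
    return d, p
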