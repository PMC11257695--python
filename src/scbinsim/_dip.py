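"""Hartigan's dip statistic and its significance test.

The dip of a distribution function F is the smallest sup-norm distance
between F and the class of unimodal distribution functions (convex
below the mode, concave above it, increasing, with at most one atom, at
the mode).  For an empirical CDF the minimisation can be restricted to
placing the mode at one of the observed support points.  With the mode
fixed at the ``m``-th unique value, the convex branch must thread the
tube ``F_n +/- eps`` to the left of the mode and the concave branch to
the right:

* each branch alone is feasible iff the greatest convex minorant of its
  upper tube bounds stays above the lower bounds (resp. the least
  concave majorant of the lower bounds stays below the uppers), which
  gives a closed-form one-sided deviation;
* the two branches must also be able to meet at the mode (convex
  endpoint <= concave start, an upward jump being allowed there); the
  extremal endpoint values follow from chord-extension bounds and the
  meeting condition is monotone in eps, so the exact per-mode deviation
  is found by bisection above the independent-branch optimum.

The one-sided deviations are monotone in the mode index (non-decreasing
on the left, non-increasing on the right), so the search starts at
their crossing and expands outward in ascending order of the relaxed
bound, stopping once it exceeds the best exact value found — an
exact computation validated against a linear-programming oracle derived
directly from the definition.

P-values come from a Monte-Carlo table of the dip's null distribution
for uniform samples (the standard calibration), stored in
:mod:`._dip_table`; between tabulated sample sizes the quantiles are
interpolated on the sqrt(n)-scaled dip.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    def _jit(fn):
        return _njit(cache=True, fastmath=False)(fn)

except Exception:  # pragma: no cover - numba is available in practice

    def _jit(fn):
        return fn


__all__ = ["dip_statistic", "dip_pvalue"]


def _unique_ecdf(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted unique support and cumulative probabilities of the ECDF."""
    xs = np.sort(np.asarray(x, dtype=float))
    vals, counts = np.unique(xs, return_counts=True)
    cum = np.cumsum(counts) / xs.size
    return vals, cum


@_jit
def _eps_left(vals, cum, m):
    """Minimal sup deviation of an independent convex branch left of mode m.

    Knots i = 0..m carry upper tube bounds c_{i-1} + eps (left limits;
    c_{-1} = 0) and lower bounds c_i - eps (c_{m-1} at the mode knot,
    whose own value belongs to the concave branch).  Feasibility is
    GCM(uppers) >= lowers and both bounds shift linearly in eps, hence
    the closed form max(lower - gcm)/2 over the knots.
    """
    if m == 0:
        return 0.0
    k = m + 1
    hx = np.empty(k)
    hy = np.empty(k)
    hn = 0
    best = 0.0
    # incremental lower hull of (vals[i], upper_i); evaluate deviation of
    # each lower bound under the final hull by a second pass
    uppers = np.empty(k)
    uppers[0] = 0.0
    for i in range(1, k):
        uppers[i] = cum[i - 1]
    lowers = np.empty(k)
    for i in range(m):
        lowers[i] = cum[i]
    lowers[m] = cum[m - 1]
    for i in range(k):
        x, y = vals[i], uppers[i]
        while hn >= 2:
            if (hy[hn - 1] - hy[hn - 2]) * (x - hx[hn - 2]) < (y - hy[hn - 2]) * (
                hx[hn - 1] - hx[hn - 2]
            ):
                break
            hn -= 1
        hx[hn] = x
        hy[hn] = y
        hn += 1
    # evaluate hull at every knot
    seg = 0
    for i in range(k):
        x = vals[i]
        while seg < hn - 2 and hx[seg + 1] <= x:
            seg += 1
        if hn == 1:
            g = hy[0]
        else:
            x0, x1 = hx[seg], hx[seg + 1]
            if x1 == x0:
                g = min(hy[seg], hy[seg + 1])
            else:
                t = (x - x0) / (x1 - x0)
                g = hy[seg] + t * (hy[seg + 1] - hy[seg])
        d = lowers[i] - g
        if d > best:
            best = d
    return best / 2.0


@_jit
def _eps_right(vals, cum, m):
    """Mirror image of :func:`_eps_left` for the concave right branch."""
    k = vals.size
    if m == k - 1:
        return 0.0
    kk = k - m
    hx = np.empty(kk)
    hy = np.empty(kk)
    hn = 0
    # mirrored: x -> -x turns the concave side into a convex problem
    uppers = np.empty(kk)  # mirrored lowers become hull points
    lowers = np.empty(kk)
    for j in range(kk):
        idx = k - 1 - j  # from the right end towards the mode
        uppers[j] = -(cum[idx])  # -(lower bound c_idx - eps)
        if idx == m:
            lowers[j] = -(cum[m])  # point bound c_m + eps (mirrored)
        else:
            lowers[j] = -(cum[idx - 1])  # -(upper bound c_{idx-1} + eps)
    best = 0.0
    for j in range(kk):
        idx = k - 1 - j
        x, y = -vals[idx], uppers[j]
        while hn >= 2:
            if (hy[hn - 1] - hy[hn - 2]) * (x - hx[hn - 2]) < (y - hy[hn - 2]) * (
                hx[hn - 1] - hx[hn - 2]
            ):
                break
            hn -= 1
        hx[hn] = x
        hy[hn] = y
        hn += 1
    seg = 0
    for j in range(kk):
        idx = k - 1 - j
        x = -vals[idx]
        while seg < hn - 2 and hx[seg + 1] <= x:
            seg += 1
        if hn == 1:
            g = hy[0]
        else:
            x0, x1 = hx[seg], hx[seg + 1]
            if x1 == x0:
                g = min(hy[seg], hy[seg + 1])
            else:
                t = (x - x0) / (x1 - x0)
                g = hy[seg] + t * (hy[seg + 1] - hy[seg])
        d = lowers[j] - g
        if d > best:
            best = d
    return best / 2.0


@_jit
def _tangent_max_slope(hx, hy, hn, qx, qy):
    """Max slope from (qx, qy) back to vertices of a convex chain."""
    lo, hi = 0, hn - 1
    while hi - lo > 2:
        m1 = lo + (hi - lo) // 3
        m2 = hi - (hi - lo) // 3
        s1 = (qy - hy[m1]) / (qx - hx[m1])
        s2 = (qy - hy[m2]) / (qx - hx[m2])
        if s1 < s2:
            lo = m1 + 1
        else:
            hi = m2
    best = -1e300
    for i in range(lo, hi + 1):
        s = (qy - hy[i]) / (qx - hx[i])
        if s > best:
            best = s
    return best


@_jit
def _conv_endpoint_min(vals, cum, m, eps):
    """Minimal feasible value at vals[m] of the convex (left) branch.

    Chord-extension bound: a convex g with g_i <= u_i and g_j >= l_j
    (i < j) must continue beyond j with at least the (u_i, l_j) chord
    slope.
    """
    if m == 0:
        return 0.0
    a = cum[m - 1] - eps
    if a < 0.0:
        a = 0.0
    hx = np.empty(m)
    hy = np.empty(m)
    hn = 0
    # hull point 0: (vals[0], u_0 = eps)
    hx[0] = vals[0]
    hy[0] = eps
    hn = 1
    for j in range(1, m):
        lj = cum[j] - eps
        s = _tangent_max_slope(hx, hy, hn, vals[j], lj)
        if s > 0.0:
            cand = lj + s * (vals[m] - vals[j])
            if cand > a:
                a = cand
        y = cum[j - 1] + eps
        x = vals[j]
        while hn >= 2:
            if (hy[hn - 1] - hy[hn - 2]) * (x - hx[hn - 2]) < (y - hy[hn - 2]) * (
                hx[hn - 1] - hx[hn - 2]
            ):
                break
            hn -= 1
        hx[hn] = x
        hy[hn] = y
        hn += 1
    return a


@_jit
def _conc_start_max(vals, cum, m, eps):
    """Maximal feasible value at vals[m] of the concave (right) branch."""
    k = vals.size
    if m == k - 1:
        return 1.0
    b = cum[m] + eps
    if b > 1.0:
        b = 1.0
    nr = k - 1 - m
    hx = np.empty(nr)
    hy = np.empty(nr)
    hn = 0
    # mirrored convex problem: hull of (-v_j, -(l_j)) from the right end
    hx[0] = -vals[k - 1]
    hy[0] = -(cum[k - 1] - eps)
    hn = 1
    for j in range(k - 2, m, -1):
        uj = cum[j - 1] + eps
        s = _tangent_max_slope(hx, hy, hn, -vals[j], -uj)
        if s > 0.0:
            cand = uj - s * (vals[j] - vals[m])
            if cand < b:
                b = cand
        x = -vals[j]
        y = -(cum[j] - eps)
        while hn >= 2:
            if (hy[hn - 1] - hy[hn - 2]) * (x - hx[hn - 2]) < (y - hy[hn - 2]) * (
                hx[hn - 1] - hx[hn - 2]
            ):
                break
            hn -= 1
        hx[hn] = x
        hy[hn] = y
        hn += 1
    return b


@_jit
def _eps_mode(vals, cum, m, cap):
    """Exact minimal sup deviation with the mode at knot m.

    ``cap`` is the best exact value found so far: when this mode cannot
    beat it (branches cannot meet even at deviation cap) a sentinel
    above cap is returned after a single feasibility sweep, avoiding
    the bisection.
    """
    e0 = _eps_left(vals, cum, m)
    er = _eps_right(vals, cum, m)
    if er > e0:
        e0 = er
    if e0 >= cap:
        return e0
    if _conv_endpoint_min(vals, cum, m, e0) <= _conc_start_max(vals, cum, m, e0) + 1e-14:
        return e0
    if cap <= 0.25 and _conv_endpoint_min(vals, cum, m, cap) > _conc_start_max(
        vals, cum, m, cap
    ) + 1e-14:
        return 1e300
    hi = cap if cap < 0.25 else 0.25
    lo = e0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _conv_endpoint_min(vals, cum, m, mid) <= _conc_start_max(vals, cum, m, mid):
            hi = mid
        else:
            lo = mid
    return hi


@_jit
def _lichao_insert(la, ls, xs, k, a, s, sign):
    """Insert line y = a + s*x into a Li Chao tree over the grid xs[0:k].

    sign=+1 keeps the upper envelope, sign=-1 the lower envelope.
    """
    node, l, r = 1, 0, k - 1
    while True:
        mid = (l + r) // 2
        if sign * (a + s * xs[mid]) > sign * (la[node] + ls[node] * xs[mid]):
            a, la[node] = la[node], a
            s, ls[node] = ls[node], s
        if l == r:
            return
        if sign * (a + s * xs[l]) > sign * (la[node] + ls[node] * xs[l]):
            node, r = 2 * node, mid
        elif sign * (a + s * xs[r]) > sign * (la[node] + ls[node] * xs[r]):
            node, l = 2 * node + 1, mid + 1
        else:
            return


@_jit
def _lichao_query(la, ls, xs, k, idx, sign):
    node, l, r = 1, 0, k - 1
    x = xs[idx]
    best = la[node] + ls[node] * x
    while l < r:
        mid = (l + r) // 2
        if idx <= mid:
            node, r = 2 * node, mid
        else:
            node, l = 2 * node + 1, mid + 1
        v = la[node] + ls[node] * x
        if sign * v > sign * best:
            best = v
    return best


@_jit
def _feasible(vals, cum, t):
    """Is there a mode placement with sup deviation <= t?

    Checks, over the window of modes whose independent branches fit
    within t, whether the minimal convex endpoint A(m) can stay below
    the maximal concave start B(m); A and B are envelopes of
    chord-extension lines independent of m, maintained in Li Chao
    trees while sweeping the mode index.
    """
    k = vals.size
    # M1: largest m with eps_left(m) <= t (eps_left(0) = 0)
    if _eps_left(vals, cum, k - 1) <= t:
        M1 = k - 1
    else:
        lo, hi = 0, k - 1
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if _eps_left(vals, cum, mid) <= t:
                lo = mid
            else:
                hi = mid
        M1 = lo
    # M0: smallest m with eps_right(m) <= t (eps_right(k-1) = 0)
    if _eps_right(vals, cum, 0) <= t:
        M0 = 0
    else:
        lo, hi = 0, k - 1
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if _eps_right(vals, cum, mid) <= t:
                hi = mid
            else:
                lo = mid
        M0 = hi
    if M0 > M1:
        return False

    A = np.empty(k)
    B = np.empty(k)
    size = 1
    while size < k:
        size *= 2
    la = np.full(4 * size, -1e300)
    ls = np.zeros(4 * size)
    # left sweep: hull of upper tube points, chord-extension lines into
    # the upper envelope; A(m) = max(c_{m-1} - t, envelope(v_m), 0)
    hx = np.empty(k)
    hy = np.empty(k)
    hx[0] = vals[0]
    hy[0] = t  # u_0
    hn = 1
    if M0 == 0:
        A[0] = 0.0
    for m in range(1, M1 + 1):
        j = m - 1
        if j >= 1:
            lj = cum[j] - t
            s = _tangent_max_slope(hx, hy, hn, vals[j], lj)
            if s > 0.0:
                _lichao_insert(la, ls, vals, k, lj - s * vals[j], s, 1.0)
            x, y = vals[j], cum[j - 1] + t
            while hn >= 2:
                if (hy[hn - 1] - hy[hn - 2]) * (x - hx[hn - 2]) < (y - hy[hn - 2]) * (
                    hx[hn - 1] - hx[hn - 2]
                ):
                    break
                hn -= 1
            hx[hn] = x
            hy[hn] = y
            hn += 1
        if m >= M0:
            a = cum[m - 1] - t
            if a < 0.0:
                a = 0.0
            env = _lichao_query(la, ls, vals, k, m, 1.0)
            if env > a:
                a = env
            A[m] = a
    # right sweep (mirrored hull), lower envelope for B
    lb = np.full(4 * size, 1e300)
    lsb = np.zeros(4 * size)
    hx[0] = -vals[k - 1]
    hy[0] = -(cum[k - 1] - t)
    hn = 1
    if M1 == k - 1:
        B[k - 1] = 1.0
    for m in range(k - 2, M0 - 1, -1):
        j = m + 1
        if j <= k - 2:
            uj = cum[j - 1] + t
            s = _tangent_max_slope(hx, hy, hn, -vals[j], -uj)
            if s > 0.0:
                _lichao_insert(lb, lsb, vals, k, uj - s * vals[j], s, -1.0)
            x, y = -vals[j], -(cum[j] - t)
            while hn >= 2:
                if (hy[hn - 1] - hy[hn - 2]) * (x - hx[hn - 2]) < (y - hy[hn - 2]) * (
                    hx[hn - 1] - hx[hn - 2]
                ):
                    break
                hn -= 1
            hx[hn] = x
            hy[hn] = y
            hn += 1
        if m <= M1:
            b = cum[m] + t
            if b > 1.0:
                b = 1.0
            env = _lichao_query(lb, lsb, vals, k, m, -1.0)
            if env < b:
                b = env
            B[m] = b
    for m in range(M0, M1 + 1):
        if A[m] <= B[m] + 1e-14:
            return True
    return False


@_jit
def _dip_core(vals, cum):
    k = vals.size
    if k == 2:
        if cum[0] < 1.0:
            t = cum[0]
            if 1.0 - t < t:
                t = 1.0 - t
            return t / 2.0
        return 0.0
    # crossing of the monotone one-sided deviations gives the relaxed
    # (independent-branch) optimum, a lower bound attained whenever the
    # two branches can already meet there
    lo, hi = 0, k - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _eps_left(vals, cum, mid) >= _eps_right(vals, cum, mid):
            hi = mid
        else:
            lo = mid
    r1 = max(_eps_left(vals, cum, lo), _eps_right(vals, cum, lo))
    r2 = max(_eps_left(vals, cum, hi), _eps_right(vals, cum, hi))
    t_lo = r1 if r1 < r2 else r2
    if _feasible(vals, cum, t_lo):
        return t_lo
    t_hi = 0.25
    for _ in range(52):
        mid = 0.5 * (t_lo + t_hi)
        if _feasible(vals, cum, mid):
            t_hi = mid
        else:
            t_lo = mid
    return t_hi


def dip_statistic(x) -> float:
    """Hartigan's dip statistic of a 1-D sample.

    Returns 0 for samples of size < 2 or constant samples (their ECDF
    is itself unimodal).  The maximal possible value is 0.25.
    """
    vals, cum = _unique_ecdf(x)
    if vals.size <= 1:
        return 0.0
    return float(_dip_core(vals, cum))


def dip_statistic_slow(x) -> float:
    """Exhaustive min over all mode placements (quadratic reference path)."""
    vals, cum = _unique_ecdf(x)
    k = vals.size
    if k <= 1:
        return 0.0
    if k == 2:
        return float(min(cum[0], 1.0 - cum[0])) / 2.0 if cum[0] < 1.0 else 0.0
    return min(float(_eps_mode(vals, cum, m, 0.25)) for m in range(k))


def _scaled_table():
    from ._dip_table import N_GRID, PROBS, QUANTILES

    n_grid = np.asarray(N_GRID, dtype=float)
    probs = np.asarray(PROBS, dtype=float)
    quant = np.asarray(QUANTILES, dtype=float)  # rows: n, cols: probs
    return n_grid, probs, quant * np.sqrt(n_grid)[:, None]


def dip_pvalue(x, *, method: str = "table", n_boot: int = 2000, seed: int = 0) -> float:
    """P-value of the dip test of unimodality.

    method="table" interpolates the frozen Monte-Carlo null quantiles of
    ``dip * sqrt(n)`` (uniform null); outside the tabulated range of n
    the nearest row is used on the scaled axis (asymptotic in n).
    method="bootstrap" simulates the uniform null afresh (seeded).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        return 1.0
    d = dip_statistic(x)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        null = np.array([dip_statistic(rng.random(n)) for _ in range(n_boot)])
        return float((np.sum(null >= d) + 1) / (n_boot + 1))
    n_grid, probs, scaled = _scaled_table()
    ds = d * np.sqrt(n)
    if n <= n_grid[0]:
        row = scaled[0]
    elif n >= n_grid[-1]:
        row = scaled[-1]
    else:
        j = int(np.searchsorted(n_grid, n))
        w = (np.log(n) - np.log(n_grid[j - 1])) / (np.log(n_grid[j]) - np.log(n_grid[j - 1]))
        row = (1 - w) * scaled[j - 1] + w * scaled[j]
    if ds <= row[0]:
        return 1.0
    if ds >= row[-1]:
        # beyond the table's resolution: below the last tabulated tail
        return float(1.0 - probs[-1]) / 2.0
    return float(1.0 - np.interp(ds, row, probs))
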