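"""Numba kernels for the CBS permutation test.

The permutation test only needs, for each shuffled series, whether the
maximal circular t-statistic reaches the observed one — not its value.
Since T^2 = E*(N-2)/(SS_tot - E) is increasing in the explained sum of
squares E = D^2 (1/k + 1/(N-k)) (D the centred partial-sum difference over
an arc of length k), "max T >= T_obs" is equivalent to "some arc attains
E >= E*", with E* = SS_tot * T_obs^2 / (T_obs^2 + N - 2). Two exact
shortcuts keep this fast:

* per permutation, an arc length k can be skipped outright when
  range(W)^2 * (1/k + 1/(N-k)) < E*, W being the centred cumulative sum —
  no arc of that length can reach E*;
* the permutation loop stops as soon as the exceedance count already
  exceeds the rejection budget floor(alpha * n_perm).
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def max_t_squared(x, min_arc, max_arc):
    """Exact max over circular arcs of T^2, with the arc (i, j].

    Returns (t2, i, j) relative to x; t2 = inf encodes a perfect split
    (zero pooled variance with nonzero mean difference). Arc lengths are
    restricted to [min_arc, N - min_arc] and, if max_arc > 0, additionally
    to k <= max_arc or k >= N - max_arc (window-limited search for very
    long intervals).
    """
    N = x.size
    m = 0.0
    for v in x:
        m += v
    m /= N
    W = np.empty(N + 1)
    W[0] = 0.0
    ss = 0.0
    for t in range(N):
        d = x[t] - m
        W[t + 1] = W[t] + d
        ss += d * d
    best_t2 = -1.0
    best_i = -1
    best_j = -1
    tiny = 1e-12 * max(ss, 1.0)
    for k in range(min_arc, N - min_arc + 1):
        if max_arc > 0 and k > max_arc and k < N - max_arc:
            continue
        ck = 1.0 / k + 1.0 / (N - k)
        for s in range(N - k + 1):
            D = W[s + k] - W[s]
            E = D * D * ck
            denom = ss - E
            if denom < tiny:
                if E > tiny:
                    return np.inf, s, s + k
                continue
            t2 = E * (N - 2) / denom
            if t2 > best_t2:
                best_t2 = t2
                best_i = s
                best_j = s + k
    if best_t2 < 0.0:
        best_t2 = 0.0
    return best_t2, best_i, best_j


@njit(cache=True)
def perm_exceed_count(x, t2_obs, n_perm, reject_limit, seed, min_arc, max_arc):
    """Count permutations whose max circular T^2 reaches t2_obs.

    Stops early (returning reject_limit + 1) once the count exceeds
    reject_limit, at which point the split can no longer be accepted.
    """
    N = x.size
    np.random.seed(seed)
    m = 0.0
    for v in x:
        m += v
    m /= N
    y = np.empty(N)
    ss = 0.0
    for t in range(N):
        y[t] = x[t] - m
        ss += y[t] * y[t]
    if ss <= 0.0 or not np.isfinite(t2_obs):
        return 0
    estar = ss * t2_obs / (t2_obs + N - 2)
    coef = np.empty(N)
    for k in range(1, N):
        coef[k] = 1.0 / k + 1.0 / (N - k)
    W = np.empty(N + 1)
    exceed = 0
    for _p in range(n_perm):
        np.random.shuffle(y)
        W[0] = 0.0
        wmin = 0.0
        wmax = 0.0
        for t in range(N):
            W[t + 1] = W[t] + y[t]
            if W[t + 1] < wmin:
                wmin = W[t + 1]
            elif W[t + 1] > wmax:
                wmax = W[t + 1]
        rng2 = (wmax - wmin) * (wmax - wmin)
        hit = False
        for k in range(min_arc, N - min_arc + 1):
            if max_arc > 0 and k > max_arc and k < N - max_arc:
                continue
            ck = coef[k]
            if rng2 * ck < estar:
                continue
            for s in range(N - k + 1):
                D = W[s + k] - W[s]
                if D * D * ck >= estar:
                    hit = True
                    break
            if hit:
                break
        if hit:
            exceed += 1
            if exceed > reject_limit:
                return exceed
    return exceed
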