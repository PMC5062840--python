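"""Iterative step fitting with a counter-fit model-selection statistic.

The fitter places change-points one at a time. At iteration k the best-fit
set tau^(k) holds the k interior change-points (plus both boundaries) that
greedily minimize the residual cost

    H = sum_i (x_i - mu_i)^2,

mu being the per-segment mean. In between every pair of adjacent best-fit
points, one *counter-fit* point is placed at the location that would best
split that interval; the counter-fit set (with the boundaries) has its own
cost Q. The step indicator

    S = Q / H

is recorded each iteration. For a genuinely step-like profile S rises to a
peak when the best fit has captured every real step while the counter-fit
is forced to sit mid-segment and fit noise; the peak height S_peak measures
how step-like the profile is (approximately 1 + Delta^2 / (4 sigma^2) for
an equal-step staircase with step height Delta and noise sigma), and the
iteration l attaining the peak estimates the number of steps.

The greedy choice uses the key identity that the next global best-fit
addition is always the counter-fit point with the largest cost reduction
d_j, so after each insertion only the two flanking sub-intervals need to be
re-scanned; with per-interval scans on prefix sums the total work is
O(n log n) in practice. ``step_fit_naive`` keeps the direct O(nK)
formulation (full scan per iteration) and serves as the reference
implementation for equivalence testing.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StepFitConfig",
    "StepFitResult",
    "fit_cost",
    "counterfit_cost",
    "best_split",
    "step_fit",
    "step_fit_naive",
    "s_peak_theory",
]


@dataclass
class StepFitConfig:
    """Iteration budget for step fitting.

    K is the maximum number of change-points to place (capped at n-1);
    record_full_trace keeps a per-iteration snapshot of the best-fit set,
    the counter-fit table and both costs, for diagnostics and testing.
    """

    K: int = 120
    record_full_trace: bool = False

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")


@dataclass
class StepFitResult:
    """Outcome of a step-fitting run.

    S_curve[k-1] is S at iteration k (1-based iterations). ``l`` is the
    iteration attaining the first maximum of S; ``tau_at_peak`` the
    best-fit change-point set at that iteration (l interior points plus
    both boundaries). ``delta_hat`` is the weighted mean absolute step
    height at iteration l and ``sigma_hat`` = sqrt(H^(l)/n) the residual
    spread. ``selected`` lists the chosen change-points in insertion
    order; ``scan_ops`` counts candidate split positions examined.
    """

    S_curve: np.ndarray
    S_peak: float
    l: int
    tau_at_peak: np.ndarray
    delta_hat: float
    sigma_hat: float
    selected: list
    scan_ops: int = 0
    trace: list = field(default_factory=list, repr=False)


def _prefix(values: np.ndarray):
    values = np.asarray(values, dtype=np.float64)
    n = len(values)
    P = np.empty(n + 1)
    P2 = np.empty(n + 1)
    P[0] = P2[0] = 0.0
    np.cumsum(values, out=P[1:])
    np.cumsum(values * values, out=P2[1:])
    return P, P2


def _sse(P: np.ndarray, P2: np.ndarray, lo: int, hi: int) -> float:
    s = P[hi] - P[lo]
    return (P2[hi] - P2[lo]) - s * s / (hi - lo)


def fit_cost(values, tau) -> float:
    """Residual cost H = sum (x_i - mu_i)^2 for the change-point set tau."""
    values = np.asarray(values, dtype=np.float64)
    from .core import validate_changepoints

    cps = validate_changepoints(tau, len(values))
    P, P2 = _prefix(values)
    return float(sum(_sse(P, P2, cps[j], cps[j + 1]) for j in range(len(cps) - 1)))


def counterfit_cost(values, counterfit_set) -> float:
    """Cost Q = sum (x_i - nu_i)^2 of the counter-fit change-point set
    (which must include both boundaries 0 and n)."""
    return fit_cost(values, counterfit_set)


def _best_split_prefix(P, P2, lo: int, hi: int):
    """Best interior split of [lo, hi): location minimizing the post-split
    SSE (ties -> smallest location) and the cost reduction achieved.
    Intervals of length < 2 have no split: (None, 0.0)."""
    length = hi - lo
    if length < 2:
        return None, 0.0
    c = np.arange(lo + 1, hi)
    nl = c - lo
    nr = hi - c
    sl = P[c] - P[lo]
    sr = P[hi] - P[c]
    sse = (P2[c] - P2[lo] - sl * sl / nl) + (P2[hi] - P2[c] - sr * sr / nr)
    i = int(np.argmin(sse))  # first minimum: smallest location on ties
    d = _sse(P, P2, lo, hi) - float(sse[i])
    return int(c[i]), max(d, 0.0)


def best_split(values, lo: int, hi: int):
    """Public wrapper: best split of values[lo:hi) and its cost reduction."""
    values = np.asarray(values, dtype=np.float64)
    if not (0 <= lo < hi <= len(values)):
        raise ValueError(f"invalid interval [{lo}, {hi}) for n={len(values)}")
    P, P2 = _prefix(values)
    return _best_split_prefix(P, P2, lo, hi)


def s_peak_theory(delta: float, sigma: float) -> float:
    """Expected S_peak for an equal-height staircase: 1 + Delta^2/(4 sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return 1.0 + delta * delta / (4.0 * sigma * sigma)


def _delta_hat(values, tau_at_peak):
    """Weighted mean absolute step height at the peak iteration: steps
    |theta_{j+1} - theta_j| weighted by sqrt(tau_{j+1} - tau_{j-1})."""
    from .core import segment_means

    seg = segment_means(values, tau_at_peak)
    theta = seg.levels
    cps = seg.changepoints
    if len(theta) < 2:
        return 0.0
    heights = np.abs(np.diff(theta))
    weights = np.sqrt(cps[2:] - cps[:-2])
    return float(np.sum(weights * heights) / np.sum(weights))


def _finalize(values, S_curve, selected, scan_ops, trace):
    values = np.asarray(values, dtype=np.float64)
    n = len(values)
    S_curve = np.asarray(S_curve, dtype=np.float64)
    l = int(np.argmax(S_curve)) + 1  # first maximum on ties
    S_peak = float(S_curve[l - 1])
    tau_at_peak = np.asarray(sorted([0, n] + list(selected[:l])), dtype=np.int64)
    delta = _delta_hat(values, tau_at_peak)
    H_l = fit_cost(values, tau_at_peak)
    sigma_hat = float(np.sqrt(H_l / n))
    return StepFitResult(
        S_curve=S_curve,
        S_peak=S_peak,
        l=l,
        tau_at_peak=tau_at_peak,
        delta_hat=delta,
        sigma_hat=sigma_hat,
        selected=list(selected),
        scan_ops=scan_ops,
        trace=trace,
    )


def _costs(P, P2, points) -> float:
    """Sum of per-interval SSEs over consecutive points (0 ... n)."""
    return float(sum(_sse(P, P2, points[j], points[j + 1]) for j in range(len(points) - 1)))


def step_fit(values, config: StepFitConfig | None = None) -> StepFitResult:
    """Incremental step fit: per iteration insert the counter-fit point with
    the largest cost reduction, then re-scan only the two flanking
    sub-intervals."""
    values = np.asarray(values, dtype=np.float64)
    n = len(values)
    if n < 4:
        raise ValueError("series too short for step fitting (need n >= 4)")
    config = config or StepFitConfig()
    K = min(config.K, n - 1)

    P, P2 = _prefix(values)
    scan_ops = 0

    # interval table, ordered by start: parallel lists of lo, hi, c, d
    lo_l, hi_l, c_l, d_l = [0], [n], [], []
    c0, d0 = _best_split_prefix(P, P2, 0, n)
    scan_ops += n - 1
    c_l.append(c0)
    d_l.append(d0)

    tau = [0, n]
    selected = []
    S_curve = []
    trace = []

    for _k in range(1, K + 1):
        d_arr = np.asarray([d if c is not None else -np.inf for c, d in zip(c_l, d_l)])
        j = int(np.argmax(d_arr))  # first maximum: smallest interval index
        if c_l[j] is None or not np.isfinite(d_arr[j]):
            break  # no interval of length >= 2 remains
        c = c_l[j]
        lo, hi = lo_l[j], hi_l[j]
        # replace interval j by its two halves
        cl, dl = _best_split_prefix(P, P2, lo, c)
        cr, dr = _best_split_prefix(P, P2, c, hi)
        scan_ops += max(c - lo - 1, 0) + max(hi - c - 1, 0)
        lo_l[j:j + 1] = [lo, c]
        hi_l[j:j + 1] = [c, hi]
        c_l[j:j + 1] = [cl, cr]
        d_l[j:j + 1] = [dl, dr]
        selected.append(c)
        tau = sorted(tau + [c])

        H = _costs(P, P2, tau)
        counter = [0] + [cc for cc in c_l if cc is not None] + [n]
        Q = _costs(P, P2, counter)
        if config.record_full_trace:
            trace.append(
                {
                    "tau": list(tau),
                    "chosen": c,
                    "counterfits": list(zip(lo_l, hi_l, c_l, d_l)),
                    "H": H,
                    "Q": Q,
                }
            )
        if H <= 0.0:
            S_curve.append(np.inf)  # degenerate perfect fit terminates the curve
            break
        S_curve.append(Q / H)

    return _finalize(values, S_curve, selected, scan_ops, trace)


def step_fit_naive(values, config: StepFitConfig | None = None) -> StepFitResult:
    """Direct O(nK) formulation: per iteration scan *all* candidate
    positions for the addition minimizing H, then recompute every
    counter-fit. Reference oracle for :func:`step_fit`."""
    values = np.asarray(values, dtype=np.float64)
    n = len(values)
    if n < 4:
        raise ValueError("series too short for step fitting (need n >= 4)")
    config = config or StepFitConfig()
    K = min(config.K, n - 1)

    P, P2 = _prefix(values)
    tau = [0, n]
    selected = []
    S_curve = []
    trace = []
    scan_ops = 0

    for _k in range(1, K + 1):
        in_tau = set(tau)
        best_i, best_H = None, np.inf
        for i in range(1, n):
            if i in in_tau:
                continue
            scan_ops += 1
            Hi = _costs(P, P2, sorted(tau + [i]))
            if Hi < best_H:
                best_H, best_i = Hi, i
        if best_i is None:
            break
        tau = sorted(tau + [best_i])
        selected.append(best_i)

        H = _costs(P, P2, tau)
        counter = [0]
        cf_table = []
        for j in range(len(tau) - 1):
            cj, dj = _best_split_prefix(P, P2, tau[j], tau[j + 1])
            cf_table.append((tau[j], tau[j + 1], cj, dj))
            if cj is not None:
                counter.append(cj)
        counter.append(n)
        Q = _costs(P, P2, counter)
        if config.record_full_trace:
            trace.append({"tau": list(tau), "chosen": best_i, "counterfits": cf_table, "H": H, "Q": Q})
        if H <= 0.0:
            S_curve.append(np.inf)
            break
        S_curve.append(Q / H)

    return _finalize(values, S_curve, selected, scan_ops, trace)
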