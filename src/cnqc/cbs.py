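"""Circular binary segmentation with permutation significance.

For an interval of the log-ratio series, the statistic is the maximal
two-sample t over all circular arcs: the arc (i, j] against its
complement, with the pooled (N-2 df) variance in the denominator. A split
is accepted when the proportion of within-interval permutations whose
maximal statistic reaches the observed one is at most ``alpha``; accepted
arcs split the interval into up to three pieces which are segmented
recursively, independently per chromosome. No merging/undo step is
applied: wave artefacts are *meant* to inflate the segment count v, which
is exactly the quantity the reliability features use.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .core import CopyNumberProfile, SegmentSet, segment_means

__all__ = ["CBSConfig", "CBSSplit", "max_t_statistic", "segment_interval", "cbs_profile"]

#: intervals longer than this use a window-limited arc search
LONG_INTERVAL_GUARD = 5000
GUARD_WINDOW = 2500


@dataclass
class CBSConfig:
    alpha: float = 0.01
    n_permutations: int = 1000
    min_width: int = 2
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if self.min_width < 1:
            raise ValueError("min_width must be >= 1")


@dataclass
class CBSSplit:
    """Maximal circular t-statistic and the inner arc (i, j] attaining it
    (0-based: the arc covers values[i:j])."""

    T: float
    i: int
    j: int


def _arc_limit(N: int) -> int:
    return GUARD_WINDOW if N > LONG_INTERVAL_GUARD else 0


def max_t_statistic(values, lo: int = 0, hi: int | None = None, min_arc: int = 1) -> CBSSplit:
    """Exact argmax of |T_ij| over circular arcs of values[lo:hi).

    T is 0 when the mean difference is 0 (constant interval) and +inf for
    a perfect split (zero pooled variance, nonzero difference). Ties break
    towards the shortest, left-most arc.
    """
    values = np.asarray(values, dtype=np.float64)
    if hi is None:
        hi = len(values)
    N = hi - lo
    if N < 4:
        raise ValueError(f"interval too short for the circular t scan (length {N} < 4)")
    t2, i, j = _kernels.max_t_squared(np.ascontiguousarray(values[lo:hi]), min_arc, _arc_limit(N))
    if i < 0:
        return CBSSplit(0.0, lo, hi)
    if j == N and i > 0:
        # an arc ending at the boundary is the same partition as the
        # left-anchored complement; canonicalize to the latter
        i, j = 0, i
    return CBSSplit(float(np.sqrt(t2)), lo + i, lo + j)


def segment_interval(values, config: CBSConfig | None = None) -> list[int]:
    """Recursive CBS on one series: sorted interior change-points.

    Deterministic given ``config.rng_seed``: each permutation test draws
    its seed from a spawned numpy SeedSequence in traversal order.
    """
    values = np.ascontiguousarray(values, dtype=np.float64)
    config = config or CBSConfig()
    n = len(values)
    found: list[int] = []
    reject_limit = int(np.floor(config.alpha * config.n_permutations))
    seed_seq = np.random.SeedSequence(config.rng_seed)
    stack = [(0, n)]
    test_idx = 0
    while stack:
        lo, hi = stack.pop()
        N = hi - lo
        if N < max(4, 2 * config.min_width):
            continue
        split = max_t_statistic(values, lo, hi, min_arc=config.min_width)
        if split.T == 0.0:
            continue
        if np.isinf(split.T):
            accept = True  # perfect split: no permutation can do better
        else:
            child = seed_seq.spawn(1)[0]  # sequential spawn: deterministic per traversal order
            seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
            exceed = _kernels.perm_exceed_count(
                values[lo:hi],
                split.T * split.T,
                config.n_permutations,
                reject_limit,
                seed,
                config.min_width,
                _arc_limit(N),
            )
            accept = exceed <= reject_limit
        test_idx += 1
        if not accept:
            continue
        i, j = split.i, split.j
        cuts = [c for c in (i, j) if lo < c < hi]
        found.extend(cuts)
        pieces = sorted({lo, hi, *cuts})
        for a, b in zip(pieces[:-1], pieces[1:]):
            stack.append((a, b))
    return sorted(found)


def cbs_profile(profile: CopyNumberProfile, config: CBSConfig | None = None):
    """Apply CBS independently per chromosome.

    Returns (SegmentSet, v) where the segment set has chromosome
    boundaries forced as change-points and v is the genome-wide segment
    count (per-chromosome change-points + 1, summed).
    """
    config = config or CBSConfig()
    boundaries = profile.chromosome_boundaries()
    all_cps = set(boundaries.tolist())
    v = 0
    for c, (lo, hi) in enumerate(zip(boundaries[:-1], boundaries[1:])):
        sub_cfg = CBSConfig(
            alpha=config.alpha,
            n_permutations=config.n_permutations,
            min_width=config.min_width,
            rng_seed=config.rng_seed + 100003 * c,
        )
        interior = segment_interval(profile.value[lo:hi], sub_cfg)
        all_cps.update(int(lo) + i for i in interior)
        v += len(interior) + 1
    segset = segment_means(profile, sorted(all_cps))
    return segset, v
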