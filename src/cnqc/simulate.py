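"""Synthetic cohorts of copy-number profiles for the reliability regimes.

Five generator regimes:

* **A** — reliable: piecewise-constant CNAs on a diploid (log ratio 0)
  baseline plus i.i.d. Gaussian noise;
* **B** — wave-contaminated: a group-A profile plus a strong
  autocorrelated AR(1) wave whose stationary amplitude is comparable to a
  single-copy CNA, burying the step signal;
* **C** — hyper-segmented: a group-A profile passed through a running
  median filter, which adds small plateau-like waves while preserving the
  step structure;
* **flat** — diploid noise only (control-like samples);
* **highDLRS** — diploid noise with the noise scale multiplied by >= 4
  (poor-DNA-quality samples).

A and flat are labeled reliable; B, C and highDLRS unreliable. Every
generator is a pure function of its spec + seed.

``segment_recovery_stats`` quantifies how well a segmenter's counts track
the truth across a cohort: Spearman rank correlation plus slope/intercept
of a Huber robust regression of detected on true counts.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.signal
import scipy.stats
import statsmodels.api as sm

from .core import CopyNumberProfile, SegmentSet

__all__ = [
    "SimProfileSpec",
    "CohortSample",
    "simulate_reliable",
    "apply_wave_artefact",
    "apply_median_filter",
    "simulate_cohort",
    "segment_recovery_stats",
    "true_segment_count",
]

GROUP_LABELS = {
    "A": "reliable",
    "B": "unreliable",
    "C": "unreliable",
    "flat": "reliable",
    "highDLRS": "unreliable",
}


@dataclass
class SimProfileSpec:
    """Study conditions for one simulated profile.

    CNA segment lengths are drawn log-uniformly over
    ``segment_length_range`` (a realistic focal-to-broad spectrum), placed
    without overlap inside single chromosomes with a gap of at least
    ``min_gap`` probes. ``wave_strength`` is the AR(1) coefficient of the
    wave process and ``wave_sd`` its innovation sd, giving a stationary
    wave amplitude wave_sd / sqrt(1 - wave_strength^2) ~ 1.3 at the
    defaults — exceeding even a full-copy change (|log2 ratio| = 1), so
    the step signal is genuinely buried and the recovered step count is
    decoupled from the truth; the wave correlation length
    1/(1 - wave_strength) ~ 100 probes. Defaults were calibrated once so
    the three cohorts reproduce the reliability regimes the features are
    designed to separate, and are exposed here in full.
    """

    n: int = 10_000
    n_chromosomes: int = 22
    n_cna_segments: tuple[int, int] | int = (5, 40)
    segment_length_range: tuple[int, int] = (5, 150)
    cna_levels: tuple[float, ...] = (-1.0, -0.58, 0.58, 1.0)
    noise_sd: float = 0.15
    wave_strength: float = 0.99
    wave_sd: float = 0.1834
    wave_model: str = "ar1"  # or "sinusoid"
    medfilter_window: int = 31
    min_gap: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n < 100:
            raise ValueError("n must be >= 100")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.medfilter_window % 2 == 0:
            raise ValueError("medfilter_window must be odd")
        if not (0.0 <= self.wave_strength < 1.0):
            raise ValueError("wave_strength must be in [0, 1)")


def _rng(seed, stream: int):
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _chromosome_labels(n: int, n_chromosomes: int):
    """Equal division of n probes into chromosomes 1..n_chromosomes."""
    edges = np.linspace(0, n, n_chromosomes + 1).round().astype(np.int64)
    labels = np.empty(n, dtype=object)
    for c in range(n_chromosomes):
        labels[edges[c]:edges[c + 1]] = str(c + 1)
    return labels, edges


def simulate_reliable(spec: SimProfileSpec):
    """Group-A generator.

    Returns (profile, truth) where ``truth`` is the true SegmentSet:
    change-points at CNA edges and chromosome boundaries, levels equal to
    the *design* levels (0 for baseline segments).
    """
    rng = _rng(spec.seed, 0)
    labels, edges = _chromosome_labels(spec.n, spec.n_chromosomes)
    if isinstance(spec.n_cna_segments, int):
        k = spec.n_cna_segments
    else:
        lo, hi = spec.n_cna_segments
        k = int(rng.integers(lo, hi + 1))
    lmin, lmax = spec.segment_length_range
    if lmax >= spec.n:
        raise ValueError("segment lengths exceed n")
    placed: list[tuple[int, int]] = []  # (start, end) probe indices
    attempts = 0
    while len(placed) < k:
        attempts += 1
        if attempts > 200_000:
            raise ValueError("could not place CNA segments (too dense for n)")
        length = int(np.round(np.exp(rng.uniform(np.log(lmin), np.log(lmax)))))
        length = max(lmin, min(length, lmax))
        start = int(rng.integers(0, spec.n - length))
        end = start + length
        chrom_idx = np.searchsorted(edges, start, side="right") - 1
        if end > edges[chrom_idx + 1]:
            continue  # CNAs stay within one chromosome
        if any(start < e + spec.min_gap and end > s - spec.min_gap for s, e in placed):
            continue
        placed.append((start, end))
    placed.sort()
    baseline = np.zeros(spec.n)
    levels = rng.choice(np.asarray(spec.cna_levels), size=k)
    for (s, e), lev in zip(placed, levels):
        baseline[s:e] = lev
    values = baseline + rng.normal(0.0, spec.noise_sd, spec.n)

    cps = {0, spec.n}
    cps.update(int(e) for e in edges)
    for s, e in placed:
        cps.add(int(s))
        cps.add(int(e))
    cps = np.asarray(sorted(cps), dtype=np.int64)
    truth = SegmentSet(cps, baseline[cps[:-1]])

    profile = CopyNumberProfile(
        sample_id=f"sim-A-{spec.seed}",
        chromosome=labels,
        position=np.arange(1, spec.n + 1, dtype=np.int64) * 1000,
        value=values,
    )
    return profile, truth


def true_segment_count(truth: SegmentSet) -> int:
    """Number of segments of the true piecewise signal (chromosome
    boundaries included), the x-axis of the recovery regressions."""
    return truth.n_segments


def apply_wave_artefact(profile: CopyNumberProfile, spec: SimProfileSpec) -> CopyNumberProfile:
    """Add a zero-mean autocorrelated wave to the values (group-B generator).

    AR(1) with coefficient ``wave_strength`` and innovation sd ``wave_sd``
    (stationary start); alternatively a random-phase sum of three
    sinusoids with matched stationary amplitude (``wave_model='sinusoid'``).
    """
    if not (0.0 < spec.wave_strength < 1.0):
        raise ValueError("wave_strength must be in (0, 1) to add a wave")
    rng = _rng(spec.seed, 1)
    n = profile.n
    stat_sd = spec.wave_sd / np.sqrt(1.0 - spec.wave_strength**2)
    if spec.wave_sd == 0.0:
        wave = np.zeros(n)
    elif spec.wave_model == "ar1":
        e = rng.normal(0.0, spec.wave_sd, n)
        e[0] = rng.normal(0.0, stat_sd)
        wave = scipy.signal.lfilter([1.0], [1.0, -spec.wave_strength], e)
    elif spec.wave_model == "sinusoid":
        t = np.arange(n)
        wave = np.zeros(n)
        for _ in range(3):
            wl = np.exp(rng.uniform(np.log(n / 50), np.log(n / 5)))
            wave += np.sin(2 * np.pi * t / wl + rng.uniform(0, 2 * np.pi))
        wave *= stat_sd / max(np.std(wave), 1e-12)
    else:
        raise ValueError(f"unknown wave_model {spec.wave_model!r}")
    return CopyNumberProfile(
        sample_id=profile.sample_id.replace("-A-", "-B-") if "-A-" in profile.sample_id else profile.sample_id + "-wave",
        chromosome=profile.chromosome.copy(),
        position=profile.position.copy(),
        value=profile.value + wave,
    )


def apply_median_filter(profile: CopyNumberProfile, window: int) -> CopyNumberProfile:
    """Running-median smoothing with reflected edges (group-C generator)."""
    if window % 2 == 0:
        raise ValueError("median filter window must be odd")
    smoothed = scipy.ndimage.median_filter(profile.value, size=window, mode="reflect")
    return CopyNumberProfile(
        sample_id=profile.sample_id.replace("-A-", "-C-") if "-A-" in profile.sample_id else profile.sample_id + "-medfilt",
        chromosome=profile.chromosome.copy(),
        position=profile.position.copy(),
        value=smoothed,
    )


@dataclass
class CohortSample:
    sample_id: str
    group: str
    label: str
    profile: CopyNumberProfile
    truth: SegmentSet
    true_segment_count: int
    n_cna: int
    seed: int


def simulate_cohort(
    n_samples_per_group: int,
    groups=("A", "B", "C", "flat", "highDLRS"),
    spec: SimProfileSpec | None = None,
) -> list[CohortSample]:
    """Generate a labeled cohort; deterministic per ``spec.seed``."""
    if n_samples_per_group < 1:
        raise ValueError("n_samples_per_group must be >= 1")
    groups = tuple(groups)
    if not groups:
        raise ValueError("empty group set")
    unknown = set(groups) - set(GROUP_LABELS)
    if unknown:
        raise ValueError(f"unknown groups {sorted(unknown)}")
    spec = spec or SimProfileSpec()
    master = np.random.SeedSequence(entropy=spec.seed, spawn_key=(99,))
    out: list[CohortSample] = []
    for g in groups:
        for i in range(n_samples_per_group):
            child_seed = int(master.spawn(1)[0].generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
            sub = dataclasses.replace(spec, seed=child_seed)
            if g in ("A", "B", "C"):
                prof, truth = simulate_reliable(sub)
                if g == "B":
                    prof = apply_wave_artefact(prof, sub)
                elif g == "C":
                    prof = apply_median_filter(prof, sub.medfilter_window)
            else:
                flat_spec = dataclasses.replace(
                    sub,
                    n_cna_segments=0,
                    noise_sd=sub.noise_sd * (4.0 if g == "highDLRS" else 1.0),
                )
                prof, truth = simulate_reliable(flat_spec)
            sid = f"sim-{g}-{i:04d}"
            prof = CopyNumberProfile(
                sample_id=sid,
                chromosome=prof.chromosome,
                position=prof.position,
                value=prof.value,
            )
            out.append(
                CohortSample(
                    sample_id=sid,
                    group=g,
                    label=GROUP_LABELS[g],
                    profile=prof,
                    truth=truth,
                    true_segment_count=true_segment_count(truth),
                    n_cna=int(np.sum(truth.levels != 0.0)),
                    seed=child_seed,
                )
            )
    return out


def segment_recovery_stats(true_counts, estimated_counts):
    """(rho, w, b): Spearman rank correlation of estimated vs true counts
    and slope/intercept of a Huber robust regression (IRLS, t = 1.345) of
    estimated on true."""
    t = np.asarray(true_counts, dtype=float)
    e = np.asarray(estimated_counts, dtype=float)
    if len(t) != len(e) or len(t) < 3:
        raise ValueError("need equal-length count lists with at least 3 entries")
    if np.all(t == t[0]):
        raise ValueError("true counts are all identical; regression is degenerate")
    rho = float(scipy.stats.spearmanr(t, e).statistic)
    X = sm.add_constant(t)
    fit = sm.RLM(e, X, M=sm.robust.norms.HuberT(t=1.345)).fit()
    b, w = float(fit.params[0]), float(fit.params[1])
    return rho, w, b
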