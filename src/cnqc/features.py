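"""The four reliability features and the medASP baseline.

A profile is summarized by (S_peak, l, v, sigma):

* S_peak, l from the step-fitting S curve — how step-like the profile is
  and how many steps it takes to get there;
* v, the number of CBS segments genome-wide — inflated by wave artefacts
  (hyper-segmentation);
* sigma, the derivative log ratio spread (DLRS) averaged within CBS
  segments: per segment, sd of successive probe differences / sqrt(2).
  Within-segment derivatives are insensitive to residual wave curvature,
  so sigma tracks the probe-level noise scale itself.

medASP — the median over sliding windows of the lag-1 autocorrelation —
is the prior-art reliability metric kept as a comparison baseline.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cbs import CBSConfig, cbs_profile
from .core import CopyNumberProfile, SegmentSet
from .stepfit import StepFitConfig, step_fit

__all__ = [
    "FeatureVector",
    "dlrs_within_segments",
    "extract_features",
    "medasp",
    "features_to_frame",
    "write_feature_table",
    "read_feature_table",
]


@dataclass
class FeatureVector:
    """The 4-tuple (S_peak, l, v, sigma) summarizing one profile."""

    sample_id: str
    S_peak: float
    l: int
    v: int
    sigma: float
    medasp: float | None = None

    def as_array(self) -> np.ndarray:
        return np.asarray([self.S_peak, float(self.l), float(self.v), self.sigma])


def dlrs_within_segments(profile, segset: SegmentSet, weighted: bool = True) -> float:
    """Probe-count-weighted mean DLRS across segments with >= 3 probes.

    DLRS_j = sd(successive differences within segment j) / sqrt(2); an
    unbiased-variance (ddof=1) sd is used. Raises if no segment has at
    least 3 probes.
    """
    values = profile.value if isinstance(profile, CopyNumberProfile) else np.asarray(profile, dtype=float)
    cps = segset.changepoints
    dlrs, weights = [], []
    for j in range(segset.n_segments):
        lo, hi = cps[j], cps[j + 1]
        if hi - lo < 3:
            continue
        d = np.diff(values[lo:hi])
        dlrs.append(np.std(d, ddof=1) / np.sqrt(2.0))
        weights.append(hi - lo)
    if not dlrs:
        raise ValueError("profile too fragmented for DLRS (no segment with >= 3 probes)")
    dlrs = np.asarray(dlrs)
    if not weighted:
        return float(np.mean(dlrs))
    weights = np.asarray(weights, dtype=float)
    return float(np.sum(weights * dlrs) / np.sum(weights))


def extract_features(
    profile: CopyNumberProfile,
    stepfit_config: StepFitConfig | None = None,
    cbs_config: CBSConfig | None = None,
    with_medasp: bool = False,
    medasp_window: int = 100,
    medasp_step: int = 25,
) -> FeatureVector:
    """Run step fitting, CBS and DLRS on one profile and assemble the
    feature vector. Deterministic given the configs' seeds."""
    sf = step_fit(profile.value, stepfit_config or StepFitConfig())
    segset, v = cbs_profile(profile, cbs_config or CBSConfig())
    sigma = dlrs_within_segments(profile, segset)
    ma = medasp(profile.value, medasp_window, medasp_step) if with_medasp else None
    return FeatureVector(
        sample_id=profile.sample_id,
        S_peak=sf.S_peak,
        l=sf.l,
        v=v,
        sigma=sigma,
        medasp=ma,
    )


def medasp(values, window: int = 100, step: int = 25, lag: int = 1) -> float:
    """Median across sliding windows of the lag-1 Pearson autocorrelation.

    Windows of ``window`` consecutive probes, stride ``step``. Windows
    where the autocorrelation is undefined (zero variance) are skipped.
    """
    values = np.asarray(values, dtype=np.float64)
    n = len(values)
    if window < 10:
        raise ValueError("window must be >= 10")
    if window > n:
        raise ValueError(f"window ({window}) exceeds series length ({n})")
    if step < 1:
        raise ValueError("step must be >= 1")
    starts = np.arange(0, n - window + 1, step)
    win = np.lib.stride_tricks.sliding_window_view(values, window)[starts]
    a = win[:, :-lag]
    b = win[:, lag:]
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = np.sum(a * b, axis=1)
    den = np.sqrt(np.sum(a * a, axis=1) * np.sum(b * b, axis=1))
    ok = den > 0
    if not np.any(ok):
        raise ValueError("autocorrelation undefined in every window (constant data)")
    return float(np.median(num[ok] / den[ok]))


FEATURE_COLUMNS = ("sample_id", "S_peak", "l", "v", "sigma")


def features_to_frame(fvs: list[FeatureVector]) -> pd.DataFrame:
    rows = []
    has_medasp = any(fv.medasp is not None for fv in fvs)
    for fv in fvs:
        row = {
            "sample_id": fv.sample_id,
            "S_peak": fv.S_peak,
            "l": fv.l,
            "v": fv.v,
            "sigma": fv.sigma,
        }
        if has_medasp:
            row["medASP"] = fv.medasp
        rows.append(row)
    return pd.DataFrame(rows)


def write_feature_table(fvs: list[FeatureVector], path) -> None:
    features_to_frame(fvs).to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> list[FeatureVector]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(
            FeatureVector(
                sample_id=str(r["sample_id"]),
                S_peak=float(r["S_peak"]),
                l=int(r["l"]),
                v=int(r["v"]),
                sigma=float(r["sigma"]),
                medasp=float(r["medASP"]) if "medASP" in df.columns else None,
            )
        )
    return out
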