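"""Domain types and probe-level I/O for copy-number profiles.

A copy-number profile is an ordered series of per-probe log2 ratios
x = {x_i}, i = 1..n, modelled as a piecewise constant signal plus i.i.d.
noise: x_i = mu_i + eps_i, where mu is constant between change-points.
A :class:`SegmentSet` holds change-points tau = {tau_0=0, ..., tau_m=n}
(0-based, half-open probe-index convention) together with per-segment
levels theta_j; when built by :func:`segment_means`, theta_j is the
arithmetic mean of the values in [tau_{j-1}, tau_j).

Probe files are tab-delimited text in the common array-probe layout
(probe id, chromosome, base position, log2 ratio); segment tables are
written SEG-style with 1-based inclusive genomic coordinates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KARYOTYPE_ORDER = tuple(str(c) for c in range(1, 23)) + ("X", "Y")

#: default column names of the tab-delimited probe file
DEFAULT_DIALECT = {
    "id": "ID",
    "chromosome": "CHRO",
    "position": "BASEPOS",
    "value": "VALUE",
}


class ProbeFileError(ValueError):
    """A probe file (or probe table) cannot be turned into a valid profile."""


def normalize_chromosome(label: object) -> str:
    """Normalize a chromosome label: strip a 'chr' prefix, upper-case X/Y."""
    s = str(label).strip()
    if s[:3].lower() == "chr":
        s = s[3:]
    if s in ("x", "y"):
        s = s.upper()
    # pandas reads an all-numeric column as ints/floats
    if s.endswith(".0"):
        s = s[:-2]
    return s


def chromosome_order_map(labels) -> dict:
    """Map chromosome labels to sort ranks: karyotype order 1..22, X, Y,
    then unknown contigs appended lexicographically (with a warning)."""
    known = {c: i for i, c in enumerate(KARYOTYPE_ORDER)}
    unknown = sorted({l for l in labels if l not in known})
    if unknown:
        warnings.warn(
            f"unknown chromosome labels appended after karyotype order: {unknown}",
            stacklevel=2,
        )
    order = dict(known)
    for j, l in enumerate(unknown):
        order[l] = len(KARYOTYPE_ORDER) + j
    return order


@dataclass
class LoadReport:
    """Bookkeeping from :func:`read_probe_file`."""

    n_rows: int = 0
    dropped: int = 0


@dataclass
class CopyNumberProfile:
    """Ordered probes (chromosome, position, log2 ratio) for one sample.

    Probes are sorted by (karyotype chromosome order, position) on
    construction; positions must be strictly increasing within a
    chromosome and all values finite.
    """

    sample_id: str
    chromosome: np.ndarray
    position: np.ndarray
    value: np.ndarray
    probe_id: np.ndarray | None = None
    load_report: LoadReport | None = field(default=None, compare=False)

    def __post_init__(self):
        chrom = np.asarray([normalize_chromosome(c) for c in np.asarray(self.chromosome)], dtype=object)
        pos = np.asarray(self.position, dtype=np.int64)
        val = np.asarray(self.value, dtype=np.float64)
        if not (len(chrom) == len(pos) == len(val)):
            raise ProbeFileError("chromosome, position and value must have equal length")
        if len(val) < 1:
            raise ProbeFileError("no parseable probe rows")
        if not np.all(np.isfinite(val)):
            raise ProbeFileError("profile values must be finite (drop non-finite probes at load)")
        order = chromosome_order_map(chrom)
        rank = np.asarray([order[c] for c in chrom])
        idx = np.lexsort((pos, rank))
        chrom, pos, val = chrom[idx], pos[idx], val[idx]
        if self.probe_id is not None:
            self.probe_id = np.asarray(self.probe_id, dtype=object)[idx]
        dup = (rank[idx][1:] == rank[idx][:-1]) & (pos[1:] == pos[:-1])
        if np.any(dup):
            offenders = [(chrom[i + 1], int(pos[i + 1])) for i in np.nonzero(dup)[0][:10]]
            raise ProbeFileError(f"duplicate (chromosome, position) pairs: {offenders}")
        self.chromosome, self.position, self.value = chrom, pos, val

    @property
    def n(self) -> int:
        return len(self.value)

    def chromosomes(self) -> list[str]:
        """Distinct chromosomes in profile order."""
        out, seen = [], set()
        for c in self.chromosome:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    def chromosome_boundaries(self) -> np.ndarray:
        """Probe-index boundaries {0, ..., n} at chromosome starts/end."""
        change = np.nonzero(self.chromosome[1:] != self.chromosome[:-1])[0] + 1
        return np.concatenate(([0], change, [self.n])).astype(np.int64)


@dataclass
class SegmentSet:
    """Change-points tau and per-segment levels theta on one profile.

    ``changepoints`` is strictly increasing with first element 0 and last
    element n (0-based, half-open); ``levels`` has one entry per segment.
    """

    changepoints: np.ndarray
    levels: np.ndarray

    def __post_init__(self):
        cps = np.asarray(self.changepoints, dtype=np.int64)
        lev = np.asarray(self.levels, dtype=np.float64)
        if cps.ndim != 1 or len(cps) < 2:
            raise ValueError("need at least two change-points (both boundaries)")
        if cps[0] != 0:
            raise ValueError("first change-point must be 0")
        if np.any(np.diff(cps) <= 0):
            raise ValueError("change-points must be strictly increasing")
        if len(lev) != len(cps) - 1:
            raise ValueError("number of levels must equal number of segments")
        self.changepoints, self.levels = cps, lev

    @property
    def n_segments(self) -> int:
        return len(self.levels)

    @property
    def counts(self) -> np.ndarray:
        return np.diff(self.changepoints)


def validate_changepoints(changepoints, n: int) -> np.ndarray:
    cps = np.asarray(changepoints, dtype=np.int64)
    if cps.ndim != 1 or len(cps) < 2:
        raise ValueError("change-point set must contain both boundaries")
    if cps[0] != 0 or cps[-1] != n:
        raise ValueError(f"change-points must start at 0 and end at n={n}")
    if np.any(cps < 0) or np.any(cps > n):
        raise ValueError("change-point outside [0, n]")
    if np.any(np.diff(cps) <= 0):
        raise ValueError("change-points must be strictly increasing")
    return cps


def segment_means(profile, changepoints) -> SegmentSet:
    """Build a SegmentSet whose levels are the per-segment means (Eq. of
    the piecewise model: theta_j = mean of x_i for i in [tau_{j-1}, tau_j)).

    ``profile`` may be a CopyNumberProfile or a plain 1-D value array.
    """
    values = profile.value if isinstance(profile, CopyNumberProfile) else np.asarray(profile, dtype=float)
    cps = validate_changepoints(changepoints, len(values))
    csum = np.concatenate(([0.0], np.cumsum(values)))
    sums = csum[cps[1:]] - csum[cps[:-1]]
    levels = sums / np.diff(cps)
    return SegmentSet(cps, levels)


def read_probe_file(path, dialect: dict | None = None, sample_id: str | None = None) -> CopyNumberProfile:
    """Read a tab-delimited probe file into a validated, sorted profile.

    Probes with non-finite values are dropped and counted in
    ``profile.load_report.dropped``; '#' lines are treated as comments.
    """
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={colmap["chromosome"]: str})
    except FileNotFoundError:
        raise
    except pd.errors.EmptyDataError:
        raise ProbeFileError(f"no parseable probe rows in {path}") from None
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise ProbeFileError(f"probe file {path} lacks required columns {missing}; has {list(df.columns)}")
    n_rows = len(df)
    if n_rows == 0:
        raise ProbeFileError(f"no parseable probe rows in {path}")
    val = pd.to_numeric(df[colmap["value"]], errors="coerce").to_numpy(dtype=float)
    pos = pd.to_numeric(df[colmap["position"]], errors="coerce").to_numpy(dtype=float)
    keep = np.isfinite(val) & np.isfinite(pos)
    dropped = int(n_rows - keep.sum())
    if keep.sum() == 0:
        raise ProbeFileError(f"no parseable probe rows in {path}")
    if sample_id is None:
        sample_id = str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return CopyNumberProfile(
        sample_id=sample_id,
        chromosome=df[colmap["chromosome"]].to_numpy()[keep],
        position=pos[keep].astype(np.int64),
        value=val[keep],
        probe_id=df[colmap["id"]].to_numpy()[keep],
        load_report=LoadReport(n_rows=n_rows, dropped=dropped),
    )


def write_probe_file(profile: CopyNumberProfile, path, dialect: dict | None = None) -> None:
    """Write a profile back to the tab-delimited probe layout."""
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    ids = profile.probe_id if profile.probe_id is not None else np.arange(profile.n)
    pd.DataFrame(
        {
            colmap["id"]: ids,
            colmap["chromosome"]: profile.chromosome,
            colmap["position"]: profile.position,
            colmap["value"]: profile.value,
        }
    ).to_csv(path, sep="\t", index=False)


SEG_COLUMNS = ("sample", "chromosome", "start", "end", "num_probes", "seg_mean")


def write_segments(segset: SegmentSet, profile: CopyNumberProfile, path) -> None:
    """Write a SEG-style table (1-based inclusive genomic coordinates).

    Segments may not cross chromosome boundaries.
    """
    cps = validate_changepoints(segset.changepoints, profile.n)
    rows = []
    for j in range(segset.n_segments):
        lo, hi = cps[j], cps[j + 1]
        if profile.chromosome[lo] != profile.chromosome[hi - 1]:
            raise ValueError(
                f"segment [{lo}, {hi}) spans chromosomes "
                f"{profile.chromosome[lo]}..{profile.chromosome[hi - 1]}; segments never cross chromosomes"
            )
        rows.append(
            (
                profile.sample_id,
                profile.chromosome[lo],
                int(profile.position[lo]),
                int(profile.position[hi - 1]),
                int(hi - lo),
                segset.levels[j],
            )
        )
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_segments(path, profile: CopyNumberProfile) -> SegmentSet:
    """Read a SEG-style table back into probe-index change-points on ``profile``."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    cps = [0]
    levels = []
    pos_index = {}
    for i in range(profile.n):
        pos_index[(profile.chromosome[i], int(profile.position[i]))] = i
    for _, row in df.iterrows():
        chrom = normalize_chromosome(row["chromosome"])
        end = pos_index[(chrom, int(row["end"]))] + 1
        cps.append(end)
        levels.append(float(row["seg_mean"]))
    cps = np.asarray(cps)
    if cps[-1] != profile.n:
        raise ValueError("segment table does not cover the profile")
    return SegmentSet(cps, np.asarray(levels))
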