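"""Windowed sequencing depth, chromosome-normalized coverage and copy number.

The central statistic is **NormCov**: per-window mean depth divided by the
per-base mean depth of the chromosome.  A NormCov of 1 means one copy of a
replicon per chromosome copy; values below 1 arise either from chromosome
polyploidy (a single-copy plasmid in a cell with P chromosome copies shows
NormCov 1/P) or from unstable inheritance (only a fraction of cells carry the
plasmid).  Disambiguating the two is the job of
:mod:`normcov.stability`; this module supplies the estimates.

Depth accumulates every aligned base of every record, so overlapping mates
double-count by default (matching the default behaviour of standard depth
tooling); pass ``double_count=False`` to subtract mate overlaps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .readsim import AlignmentSet

__all__ = [
    "CoverageTrack",
    "NormCovTrack",
    "CopyNumberEstimate",
    "depth_arrays",
    "windowed_depth",
    "normcov_tracks",
    "estimate_copy_number",
    "summarize_copy_numbers",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def _aligned_ref_length(cigar: str) -> int:
    """Reference-consumed length of a CIGAR restricted to M/=/X operations."""
    total = 0
    matched = 0
    for n, op in _CIGAR_RE.findall(cigar):
        matched += len(n) + 1
        if op in "M=X":
            total += int(n)
        else:
            raise ValueError(
                f"unsupported CIGAR operation {op!r} in {cigar!r}; "
                "only M/=/X records are accepted"
            )
    if matched != len(cigar):
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return total


@dataclass
class CoverageTrack:
    """Windowed mean depth for one replicon.

    ``values`` has columns ``start``, ``end``, ``mean_depth``; windows tile the
    replicon 0-based half-open, the last window may be partial and its mean is
    taken over its actual width, so partial windows are unbiased.
    """

    replicon: str
    window_bp: int
    values: pd.DataFrame = field(repr=False)
    total_aligned_bases: int = 0
    replicon_length: int = 0

    @property
    def mean_depth(self) -> float:
        """Per-base mean depth over the whole replicon."""
        return self.total_aligned_bases / self.replicon_length


@dataclass
class NormCovTrack:
    """Windowed chromosome-normalized coverage for one replicon.

    ``values`` has columns ``start``, ``end``, ``normcov`` where normcov is the
    window's mean depth divided by ``mu_chr``, the per-base mean depth of the
    chromosome.
    """

    replicon: str
    window_bp: int
    values: pd.DataFrame = field(repr=False)
    mu_chr: float = 0.0

    def to_tsv(self, path) -> None:
        df = self.values.copy()
        df.insert(0, "replicon", self.replicon)
        df.to_csv(path, sep="\t", index=False)


@dataclass
class CopyNumberEstimate:
    """Replicon-level copy number relative to the chromosome.

    ``normcov_mean`` (width-weighted over windows, equal to the total-depth
    ratio) is the primary estimate; the median is reported for robustness.
    The 95% CI is a percentile bootstrap over windows.
    """

    replicon: str
    normcov_mean: float
    normcov_median: float
    ci95: tuple[float, float]
    n_windows: int


def depth_arrays(alignments: AlignmentSet) -> dict[str, np.ndarray]:
    """Per-base depth array for every replicon in the alignment header.

    Every aligned base of every record contributes one unit of depth; both
    mates of a pair count independently.
    """
    starts: dict[str, list[int]] = {name: [] for name in alignments.header}
    ends: dict[str, list[int]] = {name: [] for name in alignments.header}
    for rec in alignments.records:
        length = _aligned_ref_length(rec.cigar)
        end = rec.start + length
        if rec.start < 0 or end > alignments.header[rec.replicon]:
            raise ValueError(
                f"alignment {rec.read_id}/{rec.mate} extends beyond "
                f"replicon {rec.replicon}"
            )
        starts[rec.replicon].append(rec.start)
        ends[rec.replicon].append(end)
    out: dict[str, np.ndarray] = {}
    for name, length in alignments.header.items():
        diff = np.zeros(length + 1, dtype=np.int64)
        if starts[name]:
            np.add.at(diff, np.asarray(starts[name]), 1)
            np.add.at(diff, np.asarray(ends[name]), -1)
        out[name] = np.cumsum(diff[:-1])
    return out


def _mate_overlap_correction(alignments: AlignmentSet, depth: dict[str, np.ndarray]) -> None:
    """Subtract doubly counted bases where the two mates of a pair overlap."""
    seen: dict[str, tuple[str, int, int]] = {}
    for rec in alignments.records:
        length = _aligned_ref_length(rec.cigar)
        key = rec.read_id
        if key in seen:
            other_rep, os_, oe = seen.pop(key)
            if other_rep != rec.replicon:
                continue
            lo = max(os_, rec.start)
            hi = min(oe, rec.start + length)
            if hi > lo:
                depth[rec.replicon][lo:hi] -= 1
        else:
            seen[key] = (rec.replicon, rec.start, rec.start + length)


def windowed_depth(
    alignments: AlignmentSet,
    window_bp: int = 1000,
    double_count: bool = True,
) -> dict[str, CoverageTrack]:
    """Windowed mean depth for every replicon.

    Window mean is the sum of per-base depths in the window divided by the
    window's actual width.  ``double_count=False`` subtracts mate-pair
    overlaps once (the ``--no-double-count`` behaviour).
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    depth = depth_arrays(alignments)
    if not double_count:
        _mate_overlap_correction(alignments, depth)
    tracks: dict[str, CoverageTrack] = {}
    for name, arr in depth.items():
        length = alignments.header[name]
        starts = np.arange(0, length, window_bp, dtype=np.int64)
        ends = np.minimum(starts + window_bp, length)
        sums = np.add.reduceat(arr, starts)
        means = sums / (ends - starts)
        df = pd.DataFrame({"start": starts, "end": ends, "mean_depth": means})
        tracks[name] = CoverageTrack(
            replicon=name,
            window_bp=window_bp,
            values=df,
            total_aligned_bases=int(arr.sum()),
            replicon_length=length,
        )
    return tracks


def normcov_tracks(
    tracks: dict[str, CoverageTrack], chromosome: str
) -> dict[str, NormCovTrack]:
    """Divide every window's mean depth by the chromosome per-base mean.

    μ_chr is total aligned bases on the chromosome divided by chromosome
    length (not the mean of window means — identical for full windows,
    well-defined with a partial trailing window).
    """
    if chromosome not in tracks:
        raise ValueError(f"chromosome {chromosome!r} not among coverage tracks")
    chrom = tracks[chromosome]
    mu_chr = chrom.mean_depth
    if mu_chr == 0:
        raise ValueError("chromosome has zero coverage; normalization undefined")
    out: dict[str, NormCovTrack] = {}
    for name, track in tracks.items():
        df = track.values[["start", "end"]].copy()
        df["normcov"] = track.values["mean_depth"] / mu_chr
        out[name] = NormCovTrack(
            replicon=name, window_bp=track.window_bp, values=df, mu_chr=mu_chr
        )
    return out


def estimate_copy_number(
    track: NormCovTrack,
    bootstrap_reps: int = 1000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> CopyNumberEstimate:
    """Replicon-level copy number from a NormCov track.

    The point estimate is the width-weighted mean of window NormCov values
    (algebraically the replicon's total-depth ratio).  The 95% CI is a
    percentile bootstrap over windows, resampling windows with replacement and
    recomputing the weighted mean.
    """
    df = track.values
    if len(df) == 0:
        raise ValueError("empty NormCov track")
    widths = (df["end"] - df["start"]).to_numpy(dtype=float)
    vals = df["normcov"].to_numpy(dtype=float)
    mean = float(np.average(vals, weights=widths))
    median = float(np.median(vals))
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(vals)
    reps = np.empty(bootstrap_reps)
    for b in range(bootstrap_reps):
        take = rng.integers(0, n, size=n)
        reps[b] = np.average(vals[take], weights=widths[take])
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return CopyNumberEstimate(
        replicon=track.replicon,
        normcov_mean=mean,
        normcov_median=median,
        ci95=(float(lo), float(hi)),
        n_windows=n,
    )


def summarize_copy_numbers(
    normcov: dict[str, NormCovTrack],
    bootstrap_reps: int = 1000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Per-replicon copy-number summary table (one bootstrap stream, seeded)."""
    rng = np.random.default_rng(seed)
    rows = []
    for name, track in normcov.items():
        est = estimate_copy_number(track, bootstrap_reps=bootstrap_reps, rng=rng)
        rows.append(
            {
                "replicon": name,
                "normcov_mean": est.normcov_mean,
                "normcov_median": est.normcov_median,
                "ci95_low": est.ci95[0],
                "ci95_high": est.ci95[1],
                "n_windows": est.n_windows,
            }
        )
    return pd.DataFrame(rows)
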