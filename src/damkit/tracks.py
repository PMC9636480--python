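"""Signal tracks over GATC fragments (or bins) and bedgraph I/O.

The binding track of a fusion sample is the log2 ratio of its
reads-per-million fragment signal against a Dam-only control, with a
symmetric pseudocount:

    value_i = log2( (expRPM_i + psi) / (ctrlRPM_i + psi) )

Replicate ratio tracks are quantile-normalized to each other and
averaged.  Dam-only samples additionally yield unnormalized RPM
accessibility tracks (no control), which are quantile-normalized among
themselves and averaged the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, IO, List, Sequence, Union

import numpy as np

from .counts import BinnedCoverage, FragmentCounts

__all__ = [
    "ScoredTrack",
    "RatioParams",
    "rpm_scale",
    "ratio_track",
    "quantile_normalize",
    "average_tracks",
    "damonly_track",
    "track_from_binned",
    "write_bedgraph",
    "read_bedgraph",
]


@dataclass
class ScoredTrack:
    """One real value per sorted genomic interval.

    ``intervals[chrom]`` is an ``(n, 2)`` int array of half-open intervals,
    ``values[chrom]`` the matching value vector.
    """

    intervals: Dict[str, np.ndarray]
    values: Dict[str, np.ndarray]
    label: str = ""

    def __post_init__(self) -> None:
        for chrom, iv in self.intervals.items():
            if len(iv) != len(self.values[chrom]):
                raise ValueError(f"{chrom}: interval/value length mismatch")

    @property
    def chromosomes(self) -> List[str]:
        return list(self.intervals)

    @property
    def n_intervals(self) -> int:
        return sum(len(v) for v in self.values.values())

    def flat_values(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.intervals])

    def with_flat_values(self, flat: np.ndarray, label: str = "") -> "ScoredTrack":
        out: Dict[str, np.ndarray] = {}
        i = 0
        for chrom in self.intervals:
            n = len(self.values[chrom])
            out[chrom] = np.asarray(flat[i : i + n], dtype=float)
            i += n
        return ScoredTrack(intervals=self.intervals, values=out, label=label or self.label)

    def same_intervals(self, other: "ScoredTrack") -> bool:
        if list(self.intervals) != list(other.intervals):
            return False
        return all(np.array_equal(self.intervals[c], other.intervals[c]) for c in self.intervals)

    def value_at(self, chrom: str, position: float) -> float:
        """Step-function lookup; NaN outside the covered range."""
        iv = self.intervals[chrom]
        i = int(np.searchsorted(iv[:, 0], position, side="right")) - 1
        if i < 0 or position >= iv[i, 1]:
            return float("nan")
        return float(self.values[chrom][i])


@dataclass(frozen=True)
class RatioParams:
    """Pseudocount (RPM units) for the symmetric log2 ratio."""

    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


def _intervals_from_counts(counts: FragmentCounts) -> Dict[str, np.ndarray]:
    return {
        chrom: np.array(frags, dtype=np.int64)
        for chrom, frags in counts.fmap.fragments.items()
    }


def rpm_scale(counts: FragmentCounts, label: str = "") -> ScoredTrack:
    """Reads-per-million scaling of fragment weights."""
    if counts.library_size <= 0:
        raise ValueError("library size must be positive for RPM scaling")
    factor = 1e6 / counts.library_size
    return ScoredTrack(
        intervals=_intervals_from_counts(counts),
        values={c: w * factor for c, w in counts.weights.items()},
        label=label,
    )


def ratio_track(
    exp_counts: FragmentCounts,
    ctrl_counts: FragmentCounts,
    params: RatioParams = RatioParams(),
    label: str = "",
) -> ScoredTrack:
    """log2((expRPM + psi) / (ctrlRPM + psi)) per fragment."""
    if exp_counts.fmap != ctrl_counts.fmap:
        raise ValueError("experiment and control counts use different fragment maps")
    exp_rpm = rpm_scale(exp_counts)
    ctrl_rpm = rpm_scale(ctrl_counts)
    psi = params.pseudocount
    values = {
        c: np.log2((exp_rpm.values[c] + psi) / (ctrl_rpm.values[c] + psi))
        for c in exp_rpm.intervals
    }
    return ScoredTrack(intervals=exp_rpm.intervals, values=values, label=label)


def damonly_track(ctrl_counts: FragmentCounts, label: str = "") -> ScoredTrack:
    """Unnormalized accessibility track: RPM signal of a Dam-only library."""
    return rpm_scale(ctrl_counts, label=label)


def track_from_binned(cov: BinnedCoverage, label: str = "") -> ScoredTrack:
    """View binned coverage as a ScoredTrack (for correlation QC)."""
    intervals: Dict[str, np.ndarray] = {}
    values: Dict[str, np.ndarray] = {}
    for chrom, cnt in cov.counts.items():
        length = cov.chrom_sizes[chrom]
        starts = np.arange(len(cnt), dtype=np.int64) * cov.bin_size
        ends = np.minimum(starts + cov.bin_size, length)
        intervals[chrom] = np.stack([starts, ends], axis=1)
        values[chrom] = cnt.astype(float)
    return ScoredTrack(intervals=intervals, values=values, label=label)


def quantile_normalize(tracks: Sequence[ScoredTrack]) -> List[ScoredTrack]:
    """Force all tracks onto a common value distribution by rank.

    The reference distribution is the mean of order statistics across
    tracks; ties within a track receive the mean of the reference values
    of their tied ranks, so after normalization the sorted value multisets
    of all tracks are identical and within-track order is preserved.
    """
    if not tracks:
        raise ValueError("need at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        if t.n_intervals != first.n_intervals or not t.same_intervals(first):
            raise ValueError("tracks must share one interval scheme")
    data = np.stack([t.flat_values() for t in tracks])  # (k, n)
    reference = np.sort(data, axis=1).mean(axis=0)
    out: List[ScoredTrack] = []
    for t, row in zip(tracks, data):
        order = np.argsort(row, kind="stable")
        normed = np.empty_like(row)
        normed[order] = reference
        # average reference values over runs of tied input values
        sorted_vals = row[order]
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        for a, b in zip(np.r_[0, boundaries], np.r_[boundaries, len(row)]):
            if b - a > 1:
                normed[order[a:b]] = reference[a:b].mean()
        out.append(t.with_flat_values(normed, label=t.label))
    return out


def average_tracks(tracks: Sequence[ScoredTrack], label: str = "mean") -> ScoredTrack:
    """Elementwise arithmetic mean of tracks on one interval scheme."""
    if not tracks:
        raise ValueError("need at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        if not t.same_intervals(first):
            raise ValueError("tracks must share one interval scheme")
    mean = np.mean([t.flat_values() for t in tracks], axis=0)
    return first.with_flat_values(mean, label=label)


# ---------------------------------------------------------------------------
# bedgraph I/O
# ---------------------------------------------------------------------------

PathLike = Union[str, Path, IO[str]]


def write_bedgraph(track: ScoredTrack, sink: PathLike) -> None:
    """Write 4-column bedgraph, sorted, values at 6 significant digits."""

    def _emit(fh: IO[str]) -> None:
        for chrom in track.intervals:
            iv, vals = track.intervals[chrom], track.values[chrom]
            for (s, e), v in zip(iv, vals):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")

    if hasattr(sink, "write"):
        _emit(sink)
    else:
        with open(sink, "w") as fh:
            _emit(fh)


def read_bedgraph(source: PathLike, label: str = "") -> ScoredTrack:
    """Read a bedgraph; unsorted or overlapping intervals raise ValueError."""

    def _parse(fh: IO[str]) -> ScoredTrack:
        intervals: Dict[str, List[List[int]]] = {}
        values: Dict[str, List[float]] = {}
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ValueError(f"line {lineno}: expected 4 bedgraph columns")
            chrom, s, e, v = cols[0], int(cols[1]), int(cols[2]), float(cols[3])
            if chrom in intervals and intervals[chrom]:
                prev_end = intervals[chrom][-1][1]
                if s < prev_end:
                    raise ValueError(
                        f"line {lineno}: interval {chrom}:{s}-{e} unsorted or "
                        f"overlapping previous end {prev_end}"
                    )
            intervals.setdefault(chrom, []).append([s, e])
            values.setdefault(chrom, []).append(v)
        if not intervals:
            raise ValueError("empty bedgraph")
        return ScoredTrack(
            intervals={c: np.array(iv, dtype=np.int64) for c, iv in intervals.items()},
            values={c: np.array(v) for c, v in values.items()},
            label=label,
        )

    if hasattr(source, "read"):
        return _parse(source)
    with open(source) as fh:
        return _parse(fh)
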