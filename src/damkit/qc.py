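"""Library quality analyses and the sequencing pooling calculator.

Four analyses judge whether a set of NanoDam libraries is usable:

* genome-wide Pearson correlation of binned coverage, with the keep rules
  r >= 0.9 among libraries of the same type and r >= 0.8 among pairwise
  ratio tracks of the same setup;
* library complexity: expected number of distinct reads as a function of
  sequencing depth under exact subsampling without replacement;
* fingerprint: cumulative read fraction along genome bins ranked by
  coverage (signal-rich libraries bow toward the lower right);
* signal enrichment of the averaged binding track over peak centers.

The pooling calculator converts per-library fragment size and
concentration into molarity and mixing volumes for a multiplexed
sequencing pool:

    molarity [nM]   = (1500 / average fragment size) * concentration [ng/uL]
    volume [uL]     = (target [nM] / molarity) * (final volume [uL] / n)
    water [uL]      = final volume - sum of library volumes
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .peaks import PeakRecord
from .tracks import ScoredTrack

__all__ = [
    "QcThresholds",
    "correlation_matrix",
    "flag_libraries",
    "ComplexityCurve",
    "complexity_curve",
    "FingerprintCurve",
    "fingerprint_curve",
    "EnrichmentProfile",
    "enrichment_profile",
    "PoolingInput",
    "pooling_plan",
]


@dataclass(frozen=True)
class QcThresholds:
    within_type: float = 0.9
    pairwise_comparison: float = 0.8

    def __post_init__(self) -> None:
        for v in (self.within_type, self.pairwise_comparison):
            if not (0.0 < v <= 1.0):
                raise ValueError("thresholds must lie in (0, 1]")


def correlation_matrix(tracks: Dict[str, ScoredTrack]) -> pd.DataFrame:
    """Symmetric Pearson matrix over all intervals of the given tracks.

    A zero-variance track gets NaN against everything (flagged, not an
    error); the diagonal is 1 wherever defined.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    names = list(tracks)
    data = np.stack([tracks[n].flat_values() for n in names])
    sd = data.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd == 0, np.nan, 1.0))
    return pd.DataFrame(corr, index=names, columns=names)


#: group labels whose members are pairwise ratio tracks (0.8 rule)
_RATIO_KINDS = {"ratio", "comparison", "pairwise"}


def flag_libraries(
    matrix: pd.DataFrame,
    groups: Dict[str, str],
    thresholds: QcThresholds = QcThresholds(),
) -> pd.DataFrame:
    """Keep/flag decision per sample from its correlation to same-type peers.

    *groups* maps sample -> type label; labels in {'ratio', 'comparison',
    'pairwise'} use the pairwise-comparison threshold (default 0.8), all
    others the within-type threshold (default 0.9).  A sample is flagged
    iff the median of its correlations to same-type peers is strictly
    below the threshold (the boundary is kept).  Singleton groups get the
    decision 'insufficient_replicates'.
    """
    rows = []
    for sample, group in groups.items():
        peers = [s for s, g in groups.items() if g == group and s != sample]
        threshold = (
            thresholds.pairwise_comparison if group in _RATIO_KINDS else thresholds.within_type
        )
        if not peers:
            rows.append((sample, group, np.nan, threshold, "insufficient_replicates"))
            continue
        median_r = float(np.nanmedian(matrix.loc[sample, peers].to_numpy(dtype=float)))
        decision = "kept" if median_r >= threshold else "flagged"
        rows.append((sample, group, median_r, threshold, decision))
    return pd.DataFrame(rows, columns=["sample", "group", "median_r", "threshold", "decision"])


# ---------------------------------------------------------------------------
# Complexity (c-curve analogue)
# ---------------------------------------------------------------------------

@dataclass
class ComplexityCurve:
    """(depth n, expected distinct reads d(n)) under exact subsampling."""

    depths: np.ndarray
    expected_distinct: np.ndarray


def complexity_curve(read_keys: Sequence[object], n_points: int = 20) -> ComplexityCurve:
    """Expected distinct reads at increasing depth, exactly.

    Duplicate classes are defined by identical keys (e.g. alignment
    coordinates).  For a library of N reads where class u has
    multiplicity c_u, the expected number of distinct classes in a
    uniform subsample of size n without replacement is

        d(n) = sum_u [ 1 - C(N - c_u, n) / C(N, n) ]

    computed with log-gamma for numerical stability.
    """
    keys = list(read_keys)
    if not keys:
        raise ValueError("empty read multiset")
    _unique, counts = np.unique(np.asarray(keys, dtype=object), return_counts=True)
    N = int(counts.sum())
    depths = np.unique(np.linspace(1, N, min(n_points, N)).round().astype(int))

    def log_comb(n: np.ndarray, k: np.ndarray) -> np.ndarray:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    expected = np.empty(len(depths))
    for i, n in enumerate(depths):
        ok = counts <= N - n  # classes that *can* be entirely missed
        frac = np.zeros(len(counts))
        if ok.any():
            frac[ok] = np.exp(log_comb(N - counts[ok], n) - log_comb(N, n))
        expected[i] = float(np.sum(1.0 - frac))
    return ComplexityCurve(depths=depths, expected_distinct=expected)


# ---------------------------------------------------------------------------
# Fingerprint
# ---------------------------------------------------------------------------

@dataclass
class FingerprintCurve:
    """Cumulative read fraction y over bin-rank fraction x (both in [0,1])."""

    x: np.ndarray
    y: np.ndarray

    def at(self, x: float) -> float:
        """Step-interpolated y at bin-rank fraction *x*."""
        return float(np.interp(x, np.r_[0.0, self.x], np.r_[0.0, self.y]))


def fingerprint_curve(binned_counts: np.ndarray) -> FingerprintCurve:
    """Rank bins ascending by count; y(k) = share of reads in the k lowest bins."""
    counts = np.asarray(binned_counts, dtype=float).ravel()
    if counts.size == 0:
        raise ValueError("need at least one bin")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total read count is zero")
    ranked = np.sort(counts)
    y = np.cumsum(ranked) / total
    x = np.arange(1, len(ranked) + 1) / len(ranked)
    return FingerprintCurve(x=x, y=y)


# ---------------------------------------------------------------------------
# Enrichment over peak centers
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentProfile:
    """Mean track value at offsets around peak centers."""

    offsets: np.ndarray
    mean_value: np.ndarray
    n_peaks: int

    @property
    def central_value(self) -> float:
        mid = np.argsort(np.abs(self.offsets))[:2] if len(self.offsets) % 2 == 0 else [
            int(np.argmin(np.abs(self.offsets)))
        ]
        return float(np.mean(self.mean_value[list(mid)]))

    @property
    def flank_value(self) -> float:
        return float((self.mean_value[0] + self.mean_value[-1]) / 2.0)


def enrichment_profile(
    track: ScoredTrack,
    peaks: Sequence[PeakRecord],
    half_width: int = 1000,
    n_positions: int = 50,
) -> EnrichmentProfile:
    """Sample *track* at evenly spaced offsets around each peak center and
    average across peaks (positions outside the track are ignored)."""
    if not peaks:
        raise ValueError("empty peak set")
    offsets = np.linspace(-half_width, half_width, n_positions)
    sums = np.zeros(n_positions)
    counts = np.zeros(n_positions)
    for p in peaks:
        center = (p.start + p.end) / 2.0
        for i, off in enumerate(offsets):
            v = track.value_at(p.chrom, center + off)
            if not np.isnan(v):
                sums[i] += v
                counts[i] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return EnrichmentProfile(offsets=offsets, mean_value=mean, n_peaks=len(peaks))


# ---------------------------------------------------------------------------
# Pooling calculator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoolingInput:
    """One library: average fragment size (bp) and concentration (ng/uL)."""

    name: str
    fragment_size: float
    concentration: float

    def __post_init__(self) -> None:
        if self.fragment_size <= 0 or self.concentration <= 0:
            raise ValueError(f"{self.name}: fragment size and concentration must be positive")

    @property
    def molarity(self) -> float:
        """nM, via molarity = (1500 / fragment size) * concentration."""
        return (1500.0 / self.fragment_size) * self.concentration


def pooling_plan(
    inputs: Sequence[PoolingInput],
    target_concentration: float = 20.0,
    final_volume: float = 50.0,
) -> pd.DataFrame:
    """Mixing volumes to pool libraries at the target concentration.

    Returns one row per library (molarity, volume) plus a summary row
    with the water top-up and the achieved pool concentration
    sum(molarity_i * volume_i) / final volume.  A plan needing more
    liquid than the final volume raises ``ValueError``.
    """
    if not inputs:
        raise ValueError("need at least one library")
    n = len(inputs)
    rows = []
    total_volume = 0.0
    total_nanomoles = 0.0  # nM * uL
    for lib in inputs:
        volume = (target_concentration / lib.molarity) * (final_volume / n)
        rows.append((lib.name, lib.molarity, volume))
        total_volume += volume
        total_nanomoles += lib.molarity * volume
    water = final_volume - total_volume
    if water < 0:
        raise ValueError(
            f"infeasible plan: library volumes sum to {total_volume:.3g} uL "
            f"> final volume {final_volume:.3g} uL"
        )
    achieved = total_nanomoles / final_volume
    df = pd.DataFrame(rows, columns=["library", "molarity_nM", "volume_uL"])
    df.attrs["water_uL"] = water
    df.attrs["achieved_concentration_nM"] = achieved
    return df
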