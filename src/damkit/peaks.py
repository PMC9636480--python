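"""Broad peak calling on GATC fragments, FDR consensus and reproducibility.

The caller tests each GATC fragment for enrichment of the fusion library
over its Dam-only control with a Poisson model and a local background
rate, in the spirit of broad-mode ChIP peak callers: for fragment *i*,

    lambda_i = fragment_length_i * max over background windows of the
               control read density, scaled to the experiment (library
               size times a robust median background ratio; windows: the
               fragment itself, 1 kb / 5 kb / 10 kb centered on it, and
               the genome-wide control mean as floor)

    p_i = P( Poisson(lambda_i / phi) >= round(expWeight_i / phi) )

where phi >= 1 is a genome-wide quasi-Poisson dispersion factor
absorbing the extra-Poisson variance PCR duplication introduces.

Benjamini-Hochberg q-values are computed in log10 space so that the very
small FDRs DamID signal reaches (down to -log10 FDR = 2000) survive
floating-point underflow.  Fragments with q <= 0.05 seed peaks; maximal
runs of fragments with q <= 0.1 containing at least one seed become broad
peaks.

Downstream, peaks from all pairwise fusion-vs-control comparisons are
thresholded at a fixed ladder of 41 -log10(FDR) cut-offs and merged into
one consensus set per cut-off (.mergePeak); consensus peaks present in at
least half of the per-pair sets form the reproducible set (.reproPeak).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, IO, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .counts import FragmentCounts
from .tracks import RatioParams, ratio_track

__all__ = [
    "PeakRecord",
    "PeakSet",
    "PeakCallParams",
    "ConsensusConfig",
    "default_fdr_thresholds",
    "fragment_pvalues",
    "fragment_log10_pq",
    "bh_qvalues",
    "call_broad_peaks",
    "threshold_consensus",
    "reproducible_peaks",
    "write_broadpeak",
    "read_broadpeak",
    "write_bed",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class PeakRecord:
    """broadPeak-style record; p_value/q_value are -log10 scaled."""

    chrom: str
    start: int
    end: int
    name: str
    score: int
    strand: str
    signal_value: float
    p_value: float  # -log10 p
    q_value: float  # -log10 FDR

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.name}: start {self.start} >= end {self.end}")

    def overlaps(self, other: "PeakRecord") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


class PeakSet(list):
    """A list of PeakRecords with interval helpers."""

    def sorted(self) -> "PeakSet":
        return PeakSet(sorted(self, key=lambda p: (p.chrom, p.start, p.end)))

    def total_bp(self) -> int:
        merged = merge_intervals([(p.chrom, p.start, p.end) for p in self])
        return sum(e - s for _c, s, e in merged)

    def overlaps_interval(self, chrom: str, start: int, end: int) -> bool:
        return any(p.chrom == chrom and p.start < end and start < p.end for p in self)


@dataclass(frozen=True)
class PeakCallParams:
    """Knobs of the broad caller.

    ``dispersion`` handles extra-Poisson variance (PCR duplication makes
    read counts overdispersed): 'auto' estimates a robust genome-wide
    Fano factor from the data and scales counts and lambda by it
    (quasi-Poisson); a float fixes the factor (1.0 = plain Poisson).

    ``max_link_gap`` bridges interior stretches of non-linked fragments
    shorter than this many bp (default: the 50 nt read length, below
    which single-end mapping cannot resolve a gap), so one biological
    binding region split by a sub-resolution GATC micro-fragment still
    yields one broad peak.
    """

    significant_q: float = 0.05
    linking_q: float = 0.1
    background_windows: Tuple[int, ...] = (1_000, 5_000, 10_000)
    min_significant_fragments: int = 1
    dispersion: Union[str, float] = "auto"
    max_link_gap: int = 50
    control_scaling: str = "median_ratio"
    ratio_params: RatioParams = field(default_factory=RatioParams)

    def __post_init__(self) -> None:
        if self.linking_q < self.significant_q:
            raise ValueError("linking_q must be >= significant_q")
        if not (self.dispersion == "auto" or (
            isinstance(self.dispersion, (int, float)) and self.dispersion >= 1.0
        )):
            raise ValueError("dispersion must be 'auto' or a float >= 1")
        if self.control_scaling not in ("median_ratio", "library_size"):
            raise ValueError("control_scaling must be 'median_ratio' or 'library_size'")


def default_fdr_thresholds() -> List[float]:
    """The default ladder of 41 -log10(FDR) cut-offs.

    0..5 by 1, 10..100 by 10, 125..1775 by 75, then 1900 and 2000 —
    sorted, starting at 0, ending at 2000, 41 values in total.
    """
    values = list(range(0, 6)) + list(range(10, 101, 10)) + list(range(125, 1776, 75)) + [1900, 2000]
    return [float(v) for v in values]


@dataclass(frozen=True)
class ConsensusConfig:
    fdr_thresholds: Tuple[float, ...] = tuple(default_fdr_thresholds())
    reproducible_fraction: float = 0.5
    min_overlap: int = 1

    def __post_init__(self) -> None:
        if not self.fdr_thresholds:
            raise ValueError("threshold list must not be empty")
        if list(self.fdr_thresholds) != sorted(self.fdr_thresholds):
            raise ValueError("thresholds must be sorted ascending")
        if not (0.0 < self.reproducible_fraction <= 1.0):
            raise ValueError("reproducible_fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# Per-fragment statistics
# ---------------------------------------------------------------------------

def _poisson_log10_sf(k: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """log10 P(Poisson(lam) >= k), stable far into the tail.

    scipy's log survival function underflows to -inf once the tail drops
    below the smallest normal float; those entries are recomputed from the
    series  P(X >= k) = e^-lam * lam^k / k! * sum_j prod(lam/(k+1..k+j)),
    which converges quickly when k >> lam.
    """
    k = np.asarray(k)
    lam = np.asarray(lam, dtype=float)
    logp = stats.poisson.logsf(k - 1, lam) / _LN10
    logp = np.minimum(logp, 0.0)
    bad = ~np.isfinite(logp)
    for i in np.flatnonzero(bad):
        ki, li = int(k[i]), float(lam[i])
        # log of the leading term e^-lam lam^k / k!
        log_term = (-li + ki * math.log(li) - math.lgamma(ki + 1)) / _LN10
        # series correction sum_{j>=0} prod_{m=1..j} lam/(k+m)
        total, term, m = 1.0, 1.0, 1
        while True:
            term *= li / (ki + m)
            total += term
            m += 1
            if term < 1e-16 * total or m > 100_000:
                break
        logp[i] = min(log_term + math.log10(total), 0.0)
    return logp

def _median_ratio(
    exp_counts: FragmentCounts, ctrl_counts: FragmentCounts, lib_scale: float
) -> float:
    """Robust background normalization factor between the two libraries.

    A fusion library spends part of its reads on bound fragments, so its
    *background* runs below the library-size-scaled control; dividing by
    library size alone then mis-centers the null.  The median over
    fragments of expWeight / (lib-scaled ctrlWeight) estimates the true
    background ratio while ignoring the minority of bound fragments —
    the same idea as the background-ratio normalization of established
    DamID pipelines.
    """
    k = np.concatenate([exp_counts.weights[c] for c in exp_counts.fmap.chromosomes])
    cw = np.concatenate([ctrl_counts.weights[c] for c in ctrl_counts.fmap.chromosomes])
    ok = cw * lib_scale >= 1.0
    if not ok.any():
        return 1.0
    r = float(np.median(k[ok] / (cw[ok] * lib_scale)))
    return r if r > 0 else 1.0


# median of the chi-squared distribution with one degree of freedom;
# under a well-calibrated Poisson model, median over fragments of
# (k - lambda)^2 / lambda approaches this value
_CHI2_1_MEDIAN = 0.4549364231195724


def _dispersion_factor(
    k_by_chrom: Dict[str, np.ndarray],
    mu_by_chrom: Dict[str, np.ndarray],
    dispersion: Union[str, float],
) -> float:
    """Genome-wide Fano factor estimate, robust to enriched fragments.

    *mu* is a smooth local background expectation per fragment.  Because a
    fusion library concentrates part of its reads in bound regions, its
    background runs systematically below the library-size-scaled control;
    the expectation is therefore recentred by the median count/expectation
    ratio before residuals are formed:

        r   = median_i( k_i / mu_i )
        phi = median_i[ (k_i - r mu_i)^2 / (r mu_i) ] / median(chi2_1)

    clipped at 1 (never sharpen below Poisson).  Medians ignore the few
    truly bound fragments, so phi reflects background overdispersion
    (e.g. from PCR duplication) only.
    """
    if dispersion != "auto":
        return float(dispersion)
    k = np.concatenate([v.astype(float) for v in k_by_chrom.values()])
    mu = np.concatenate(list(mu_by_chrom.values()))
    ok = mu > 0
    if not ok.any():
        return 1.0
    k, mu = k[ok], mu[ok]
    r = float(np.median(k / mu))
    if r <= 0:
        return 1.0
    resid = (k - r * mu) ** 2 / (r * mu)
    return max(1.0, float(np.median(resid)) / _CHI2_1_MEDIAN)


def _window_density(
    bounds: np.ndarray, cumw: np.ndarray, centers: np.ndarray, width: int, chrom_len: int
) -> np.ndarray:
    """Mean control density (weight per bp) in windows of *width* centered
    on *centers*, treating each fragment's weight as uniform over its span."""
    a = np.clip(centers - width / 2.0, 0.0, chrom_len)
    b = np.clip(centers + width / 2.0, 0.0, chrom_len)
    wa = np.interp(a, bounds, cumw)
    wb = np.interp(b, bounds, cumw)
    span = np.maximum(b - a, 1.0)
    return (wb - wa) / span


def fragment_log10_pq(
    exp_counts: FragmentCounts,
    ctrl_counts: FragmentCounts,
    params: PeakCallParams = PeakCallParams(),
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Per-fragment log10 p and log10 q (both <= 0), computed in log space."""
    if exp_counts.fmap != ctrl_counts.fmap:
        raise ValueError("experiment and control counts use different fragment maps")
    if exp_counts.library_size <= 0 or ctrl_counts.library_size <= 0:
        raise ValueError("both libraries must be non-empty")
    fmap = exp_counts.fmap
    scale = exp_counts.library_size / ctrl_counts.library_size
    if params.control_scaling == "median_ratio":
        scale *= _median_ratio(exp_counts, ctrl_counts, scale)
    genome_len = sum(fmap.chrom_lengths.values())
    floor_density = ctrl_counts.total_weight * scale / genome_len

    lam_by_chrom: Dict[str, np.ndarray] = {}
    k_by_chrom: Dict[str, np.ndarray] = {}
    mu_by_chrom: Dict[str, np.ndarray] = {}
    for chrom in fmap.chromosomes:
        frags = np.array(fmap.fragments[chrom], dtype=np.int64)
        starts, ends = frags[:, 0], frags[:, 1]
        lengths = (ends - starts).astype(float)
        centers = (starts + ends) / 2.0
        chrom_len = fmap.chrom_lengths[chrom]
        ctrl_w = ctrl_counts.weights[chrom] * scale
        bounds = np.concatenate([starts, [chrom_len]]).astype(float)
        cumw = np.concatenate([[0.0], np.cumsum(ctrl_w)])

        density = np.maximum(ctrl_w / lengths, floor_density)
        for width in params.background_windows:
            density = np.maximum(
                density, _window_density(bounds, cumw, centers, width, chrom_len)
            )
        lam_by_chrom[chrom] = density * lengths
        k_by_chrom[chrom] = np.round(exp_counts.weights[chrom]).astype(int)
        mu_by_chrom[chrom] = ctrl_w

    phi = _dispersion_factor(k_by_chrom, mu_by_chrom, params.dispersion)
    log10p: Dict[str, np.ndarray] = {}
    for chrom in fmap.chromosomes:
        lam = lam_by_chrom[chrom] / phi
        k = np.round(k_by_chrom[chrom] / phi).astype(int)
        log10p[chrom] = _poisson_log10_sf(k, lam)

    flat = np.concatenate([log10p[c] for c in fmap.chromosomes])
    flat_q = _bh_log10(flat)
    log10q: Dict[str, np.ndarray] = {}
    i = 0
    for chrom in fmap.chromosomes:
        n = len(log10p[chrom])
        log10q[chrom] = flat_q[i : i + n]
        i += n
    return log10p, log10q


def fragment_pvalues(
    exp_counts: FragmentCounts,
    ctrl_counts: FragmentCounts,
    params: PeakCallParams = PeakCallParams(),
) -> Dict[str, np.ndarray]:
    """Per-fragment upper-tail Poisson p-values in (0, 1]."""
    log10p, _ = fragment_log10_pq(exp_counts, ctrl_counts, params)
    return {c: np.maximum(10.0 ** v, np.finfo(float).tiny) for c, v in log10p.items()}


def _bh_log10(log10p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up on log10 p-values, returning log10 q."""
    n = len(log10p)
    if n == 0:
        return log10p.copy()
    order = np.argsort(log10p, kind="stable")
    adj = log10p[order] + np.log10(n / np.arange(1, n + 1))
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 0.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values with enforced monotonicity.

    Input p-values must lie in (0, 1]; output q-values do too.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (p.min() <= 0.0 or p.max() > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    return 10.0 ** _bh_log10(np.log10(p))


# ---------------------------------------------------------------------------
# Broad peaks
# ---------------------------------------------------------------------------

def call_broad_peaks(
    exp_counts: FragmentCounts,
    ctrl_counts: FragmentCounts,
    params: PeakCallParams = PeakCallParams(),
    name_prefix: str = "peak",
) -> PeakSet:
    """Call broad peaks: runs of linking-level fragments around seeds.

    Fragments with q <= ``significant_q`` are seeds; each maximal run of
    consecutive fragments with q <= ``linking_q`` containing at least
    ``min_significant_fragments`` seeds becomes one peak.  Runs separated
    by non-linked interior stretches shorter than ``max_link_gap`` bp are
    bridged into one peak.  The peak's p/q are the -log10 of the best
    linked fragment in the run; the signal value is the mean log2 ratio
    over the peak span.
    """
    log10p, log10q = fragment_log10_pq(exp_counts, ctrl_counts, params)
    ratio = ratio_track(exp_counts, ctrl_counts, params.ratio_params)
    fmap = exp_counts.fmap
    log_sig = math.log10(params.significant_q)
    log_link = math.log10(params.linking_q)
    peaks = PeakSet()
    n = 0
    for chrom in fmap.chromosomes:
        frags = fmap.fragments[chrom]
        q = log10q[chrom]
        p = log10p[chrom]
        linked = q <= log_link
        seed = q <= log_sig
        # maximal runs [i, j] of linked fragments
        runs: List[Tuple[int, int]] = []
        i = 0
        while i < len(frags):
            if not linked[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(frags) and linked[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        # bridge runs separated by sub-resolution gaps
        merged_runs: List[Tuple[int, int]] = []
        for run in runs:
            if merged_runs and frags[run[0]][0] - frags[merged_runs[-1][1]][1] < params.max_link_gap:
                merged_runs[-1] = (merged_runs[-1][0], run[1])
            else:
                merged_runs.append(run)
        for i, j in merged_runs:
            sel = linked[i : j + 1]
            if int(seed[i : j + 1].sum()) < params.min_significant_fragments:
                continue
            n += 1
            best_p = -float(p[i : j + 1][sel].min())
            best_q = -float(q[i : j + 1][sel].min())
            peaks.append(
                PeakRecord(
                    chrom=chrom,
                    start=frags[i][0],
                    end=frags[j][1],
                    name=f"{name_prefix}_{n}",
                    score=min(1000, int(round(10 * best_q))),
                    strand=".",
                    signal_value=float(ratio.values[chrom][i : j + 1].mean()),
                    p_value=best_p,
                    q_value=best_q,
                )
            )
    return peaks


# ---------------------------------------------------------------------------
# Consensus and reproducibility
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Sequence[Tuple[str, int, int]]) -> List[Tuple[str, int, int]]:
    """Merge intervals overlapping by >= 1 bp (sorted output)."""
    merged: List[Tuple[str, int, int]] = []
    for chrom, s, e in sorted(intervals):
        if merged and merged[-1][0] == chrom and s < merged[-1][2]:
            c, ms, me = merged[-1]
            merged[-1] = (c, ms, max(me, e))
        else:
            merged.append((chrom, s, e))
    return merged


def _threshold(peak_set: Sequence[PeakRecord], fdr: float) -> PeakSet:
    return PeakSet(p for p in peak_set if p.q_value >= fdr)


def threshold_consensus(
    peak_sets_by_pair: Dict[str, Sequence[PeakRecord]],
    cfg: ConsensusConfig = ConsensusConfig(),
) -> Dict[float, PeakSet]:
    """One merged consensus peak set per -log10(FDR) cut-off.

    At cut-off F, records with q_value >= F from all pairwise sets are
    pooled, sorted and merged (>= 1 bp overlap).  Merged records keep the
    best p/q and the mean signal of their members.
    """
    if not peak_sets_by_pair:
        raise ValueError("need at least one peak set")
    out: Dict[float, PeakSet] = {}
    for fdr in cfg.fdr_thresholds:
        survivors: List[PeakRecord] = []
        for pair in peak_sets_by_pair.values():
            survivors.extend(_threshold(pair, fdr))
        merged = PeakSet()
        for i, (chrom, s, e) in enumerate(merge_intervals([(p.chrom, p.start, p.end) for p in survivors]), 1):
            members = [p for p in survivors if p.chrom == chrom and p.start < e and s < p.end]
            merged.append(
                PeakRecord(
                    chrom=chrom,
                    start=s,
                    end=e,
                    name=f"merge_{i}",
                    score=min(1000, int(round(10 * max(p.q_value for p in members)))),
                    strand=".",
                    signal_value=float(np.mean([p.signal_value for p in members])),
                    p_value=max(p.p_value for p in members),
                    q_value=max(p.q_value for p in members),
                )
            )
        out[fdr] = merged
    return out


def reproducible_peaks(
    peak_sets_by_pair: Dict[str, Sequence[PeakRecord]],
    cfg: ConsensusConfig = ConsensusConfig(),
    at_threshold: float = 0.0,
    mode: str = "per_threshold",
) -> PeakSet:
    """Consensus peaks occurring in at least ``reproducible_fraction`` of
    the per-pair peak sets (>= ``min_overlap`` bp overlap counts as
    occurrence; 'at least' is inclusive, so exactly 50 % is retained).

    ``mode='per_threshold'`` (default) counts occurrence against the
    per-pair sets thresholded at ``at_threshold``; ``mode='raw'`` counts
    against the unthresholded per-pair sets.
    """
    if len(peak_sets_by_pair) < 2:
        raise ValueError("need at least two peak sets for reproducibility")
    if mode not in ("per_threshold", "raw"):
        raise ValueError(f"unknown mode {mode!r}")
    consensus = threshold_consensus(
        peak_sets_by_pair,
        ConsensusConfig(
            fdr_thresholds=(at_threshold,),
            reproducible_fraction=cfg.reproducible_fraction,
            min_overlap=cfg.min_overlap,
        ),
    )[at_threshold]
    if mode == "per_threshold":
        reference = {pair: _threshold(ps, at_threshold) for pair, ps in peak_sets_by_pair.items()}
    else:
        reference = {pair: PeakSet(ps) for pair, ps in peak_sets_by_pair.items()}
    needed = cfg.reproducible_fraction * len(peak_sets_by_pair)
    kept = PeakSet()
    for cand in consensus:
        occurrences = sum(
            1
            for ps in reference.values()
            if any(
                p.chrom == cand.chrom
                and min(p.end, cand.end) - max(p.start, cand.start) >= cfg.min_overlap
                for p in ps
            )
        )
        if occurrences >= needed:
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# broadPeak / BED I/O
# ---------------------------------------------------------------------------

PathLike = Union[str, Path, IO[str]]


def write_broadpeak(peaks: Sequence[PeakRecord], sink: PathLike) -> None:
    """Write 9-column broadPeak (BED6+3), sorted, q at >= 4 significant digits."""

    def _emit(fh: IO[str]) -> None:
        for p in PeakSet(peaks).sorted():
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score}\t{p.strand}\t"
                f"{p.signal_value:.5g}\t{p.p_value:.5g}\t{p.q_value:.5g}\n"
            )

    if hasattr(sink, "write"):
        _emit(sink)
    else:
        with open(sink, "w") as fh:
            _emit(fh)


def read_broadpeak(source: PathLike) -> PeakSet:
    """Read broadPeak; wrong column counts or unsorted input raise ValueError."""

    def _parse(fh: IO[str]) -> PeakSet:
        peaks = PeakSet()
        prev: Optional[Tuple[str, int]] = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"line {lineno}: expected 9 broadPeak columns, got {len(cols)}")
            rec = PeakRecord(
                chrom=cols[0],
                start=int(cols[1]),
                end=int(cols[2]),
                name=cols[3],
                score=int(cols[4]),
                strand=cols[5],
                signal_value=float(cols[6]),
                p_value=float(cols[7]),
                q_value=float(cols[8]),
            )
            key = (rec.chrom, rec.start)
            if prev is not None and key < prev:
                raise ValueError(f"line {lineno}: records not sorted")
            prev = key
            peaks.append(rec)
        return peaks

    if hasattr(source, "read"):
        return _parse(source)
    with open(source) as fh:
        return _parse(fh)


def write_bed(peaks: Sequence[PeakRecord], sink: PathLike) -> None:
    """BED6 projection of a peak set."""

    def _emit(fh: IO[str]) -> None:
        for p in PeakSet(peaks).sorted():
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score}\t{p.strand}\n")

    if hasattr(sink, "write"):
        _emit(sink)
    else:
        with open(sink, "w") as fh:
            _emit(fh)
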