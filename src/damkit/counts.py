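"""Read placement and per-GATC-fragment / per-bin accumulation.

Two routes produce alignments: an exact-match toy aligner for simulated
genomes (a read is placed iff its sequence or reverse complement occurs
exactly once in the genome) and ingestion of a pre-aligned SAM text file.
Alignments are then extended in their strand direction — 300 bp for
fragment counting, 150 bp for binned coverage — before accumulation.

Fragment counting distributes each read's unit weight over the GATC
fragments it overlaps, proportionally to the overlap length, so that the
total weight equals the aligned read count exactly (an ``all_overlap``
mode that gives every overlapped fragment a full count is also provided).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, IO, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .gatcmap import GatcFragmentMap, GenomeSequence
from .readprep import ReadRecord

__all__ = [
    "Alignment",
    "AlignStats",
    "GenomeIndex",
    "align_exact",
    "read_sam",
    "write_sam",
    "FragmentCounts",
    "count_fragments",
    "BinnedCoverage",
    "bin_coverage",
    "read_chrom_sizes",
    "write_chrom_sizes",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Alignment:
    chrom: str
    start: int  # 0-based
    strand: str  # '+' or '-'
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class AlignStats:
    aligned: int = 0
    unaligned: int = 0
    multimapped: int = 0


class GenomeIndex:
    """Seed-and-verify exact substring index over both strands.

    Seeds of ``seed_length`` nt are hashed; a query is verified against
    every seed hit and counted as placed only when it matches the genome
    exactly once across both strands.
    """

    def __init__(self, genome: GenomeSequence, seed_length: int = 30) -> None:
        self.genome = genome
        self.seed_length = seed_length
        self._rc = {chrom: _revcomp(seq) for chrom, seq in genome.items()}
        self._seeds: Dict[str, List[Tuple[str, int, str]]] = {}
        for chrom, seq in genome.items():
            L = len(seq)
            for s, strand in ((seq, "+"), (self._rc[chrom], "-")):
                for i in range(0, L - seed_length + 1):
                    self._seeds.setdefault(s[i : i + seed_length], []).append((chrom, i, strand))

    def occurrences(self, read: str) -> List[Alignment]:
        """All exact occurrences of *read* (forward hits on either strand)."""
        k = self.seed_length
        hits: List[Alignment] = []
        if len(read) < k:
            for chrom in self.genome:
                for s, strand in ((self.genome[chrom], "+"), (self._rc[chrom], "-")):
                    pos = s.find(read)
                    while pos != -1:
                        hits.append(self._to_forward(chrom, pos, strand, len(read)))
                        pos = s.find(read, pos + 1)
            return hits
        for chrom, i, strand in self._seeds.get(read[:k], ()):
            seq = self.genome[chrom] if strand == "+" else self._rc[chrom]
            if seq[i : i + len(read)] == read:
                hits.append(self._to_forward(chrom, i, strand, len(read)))
        return hits

    def _to_forward(self, chrom: str, pos: int, strand: str, length: int) -> Alignment:
        if strand == "+":
            return Alignment(chrom, pos, "+", length)
        L = len(self.genome[chrom])
        return Alignment(chrom, L - pos - length, "-", length)


def align_exact(
    reads: Iterable[ReadRecord],
    genome: Union[GenomeSequence, GenomeIndex],
) -> Tuple[List[Alignment], AlignStats]:
    """Place each read at its unique exact occurrence in the genome.

    Reads matching more than once (either strand) count as multimapped,
    reads matching nowhere as unaligned; neither is emitted.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    alignments: List[Alignment] = []
    stats = AlignStats()
    for read in reads:
        occ = index.occurrences(read.sequence)
        if len(occ) == 1:
            alignments.append(occ[0])
            stats.aligned += 1
        elif not occ:
            stats.unaligned += 1
        else:
            stats.multimapped += 1
    return alignments, stats


# ---------------------------------------------------------------------------
# SAM text subset
# ---------------------------------------------------------------------------

def read_sam(source: Union[str, Path, IO[str]]) -> List[Alignment]:
    """Ingest a SAM text file, using FLAG, RNAME, POS and SEQ length only.

    Unmapped records (FLAG 0x4) are skipped; FLAG 0x10 sets strand '-';
    POS is converted from 1-based to 0-based.  A record with fewer than
    the 11 mandatory columns raises ``ValueError`` with its line number.
    """

    def _parse(fh: IO[str]) -> List[Alignment]:
        alignments: List[Alignment] = []
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            cols = line.split("\t")
            if len(cols) < 11:
                raise ValueError(
                    f"line {lineno}: SAM record has {len(cols)} columns, 11 required"
                )
            flag = int(cols[1])
            if flag & 0x4:
                continue
            strand = "-" if flag & 0x10 else "+"
            alignments.append(
                Alignment(chrom=cols[2], start=int(cols[3]) - 1, strand=strand, length=len(cols[9]))
            )
        return alignments

    if hasattr(source, "read"):
        return _parse(source)
    with open(source) as fh:
        return _parse(fh)


def write_sam(
    alignments: Sequence[Alignment],
    chrom_sizes: Dict[str, int],
    sink: Union[str, Path, IO[str]],
    genome: Optional[GenomeSequence] = None,
) -> None:
    """Write alignments as minimal SAM text (SEQ from *genome* if given)."""

    def _emit(fh: IO[str]) -> None:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, length in chrom_sizes.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for i, a in enumerate(alignments):
            flag = 16 if a.strand == "-" else 0
            if genome is not None:
                seq = genome[a.chrom][a.start : a.end]
                if a.strand == "-":
                    seq = _revcomp(seq)
            else:
                seq = "N" * a.length
            fh.write(
                f"read{i}\t{flag}\t{a.chrom}\t{a.start + 1}\t255\t{a.length}M\t*\t0\t0\t{seq}\t*\n"
            )

    if hasattr(sink, "write"):
        _emit(sink)
    else:
        with open(sink, "w") as fh:
            _emit(fh)


# ---------------------------------------------------------------------------
# Fragment counting
# ---------------------------------------------------------------------------

@dataclass
class FragmentCounts:
    """Per-GATC-fragment read weights for one library."""

    fmap: GatcFragmentMap
    weights: Dict[str, np.ndarray]
    library_size: int

    @property
    def total_weight(self) -> float:
        return float(sum(w.sum() for w in self.weights.values()))

    def flat_weights(self) -> np.ndarray:
        return np.concatenate([self.weights[c] for c in self.fmap.chromosomes])


def _extend(aln: Alignment, extension: int, chrom_len: int) -> Tuple[int, int]:
    """Extend *aln* to ``max(extension, read length)`` bp in strand
    direction, clipped at the chromosome ends."""
    ext = max(extension, aln.length)
    if aln.strand == "+":
        a, b = aln.start, aln.start + ext
    else:
        a, b = aln.end - ext, aln.end
    return max(a, 0), min(b, chrom_len)


def count_fragments(
    alignments: Sequence[Alignment],
    fmap: GatcFragmentMap,
    extension: int = 300,
    mode: str = "fractional",
) -> FragmentCounts:
    """Accumulate extended reads into per-fragment weights.

    ``fractional`` (default) splits each read's unit weight over the
    fragments it overlaps in proportion to overlap length, so total weight
    equals the aligned read count; ``all_overlap`` gives each overlapped
    fragment a full count.
    """
    if mode not in ("fractional", "all_overlap"):
        raise ValueError(f"unknown mode {mode!r}")
    boundaries = {
        chrom: np.array([s for s, _e in frags] + [frags[-1][1]], dtype=np.int64)
        for chrom, frags in fmap.fragments.items()
    }
    weights = {chrom: np.zeros(len(frags)) for chrom, frags in fmap.fragments.items()}
    for aln in alignments:
        if aln.chrom not in weights:
            raise ValueError(f"alignment on unknown chromosome {aln.chrom!r}")
        a, b = _extend(aln, extension, fmap.chrom_lengths[aln.chrom])
        bounds = boundaries[aln.chrom]
        lo = int(np.searchsorted(bounds, a, side="right")) - 1
        hi = int(np.searchsorted(bounds, b, side="left"))  # fragments lo..hi-1 overlap
        w = weights[aln.chrom]
        if mode == "all_overlap":
            w[lo:hi] += 1.0
        else:
            span = b - a
            for f in range(lo, hi):
                ov = min(b, bounds[f + 1]) - max(a, bounds[f])
                w[f] += ov / span
    return FragmentCounts(fmap=fmap, weights=weights, library_size=len(alignments))


# ---------------------------------------------------------------------------
# Binned coverage
# ---------------------------------------------------------------------------

@dataclass
class BinnedCoverage:
    """Per-bin counts of extended-read presence (>=1 bp overlap per bin)."""

    bin_size: int
    extension: int
    counts: Dict[str, np.ndarray]
    chrom_sizes: Dict[str, int]

    def flat_counts(self) -> np.ndarray:
        return np.concatenate([self.counts[c] for c in self.counts])


def bin_coverage(
    alignments: Sequence[Alignment],
    chrom_sizes: Dict[str, int],
    bin_size: int = 500,
    extension: int = 150,
) -> BinnedCoverage:
    """Count extended reads per fixed-width genome bin (last bin may be short)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    counts = {
        chrom: np.zeros(-(-length // bin_size), dtype=np.int64)
        for chrom, length in chrom_sizes.items()
    }
    for aln in alignments:
        if aln.chrom not in chrom_sizes:
            raise ValueError(f"alignment on unknown chromosome {aln.chrom!r}")
        a, b = _extend(aln, extension, chrom_sizes[aln.chrom])
        if b <= a:
            continue
        counts[aln.chrom][a // bin_size : (b - 1) // bin_size + 1] += 1
    return BinnedCoverage(bin_size=bin_size, extension=extension, counts=counts, chrom_sizes=dict(chrom_sizes))


# ---------------------------------------------------------------------------
# chrom.sizes TSV
# ---------------------------------------------------------------------------

def read_chrom_sizes(source: Union[str, Path, IO[str]]) -> Dict[str, int]:
    def _parse(fh: IO[str]) -> Dict[str, int]:
        sizes: Dict[str, int] = {}
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            name, length = line.split("\t")[:2]
            sizes[name] = int(length)
        return sizes

    if hasattr(source, "read"):
        return _parse(source)
    with open(source) as fh:
        return _parse(fh)


def write_chrom_sizes(sizes: Dict[str, int], sink: Union[str, Path, IO[str]]) -> None:
    def _emit(fh: IO[str]) -> None:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")

    if hasattr(sink, "write"):
        _emit(sink)
    else:
        with open(sink, "w") as fh:
            _emit(fh)
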