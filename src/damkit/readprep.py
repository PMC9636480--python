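"""FASTQ quality control: adaptor trimming and length filtering.

DamID libraries carry the DamID PCR primer at the 5' end of the genomic
insert and may run into the sequencing index adaptor at the 3' end.  The
trimmer removes both; the length filter then keeps reads of 30–50 nt,
the window in which a 50 nt single-end DamID read is informative after
trimming.

Adaptor matching follows the usual convention of read trimmers: a 5'
adaptor may be present in full or as a suffix overlapping the read start;
a 3' adaptor may occur in full anywhere (everything from there on is cut)
or as a prefix overlapping the read end.  Matches tolerate a mismatch
rate of 0.1 and require a minimum overlap of 3 nt; both are configurable.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, IO, Iterable, List, Sequence, Tuple, Union

__all__ = [
    "ReadRecord",
    "AdaptorSet",
    "DAMID_PCR_PRIMER",
    "INDEX_ADAPTOR_STEM",
    "THREE_PRIME_ADAPTOR",
    "trim_read",
    "length_filter",
    "FilterCounts",
    "read_fastq",
    "write_fastq",
    "qc_summary",
    "write_qc_report",
]

#: 5' DamID PCR primer present upstream of every genomic insert.
DAMID_PCR_PRIMER = "GGTCGCGGCCGAGGATC"
#: Shared stem of the indexed sequencing adaptors.
INDEX_ADAPTOR_STEM = "GATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
#: 3' adaptor as it appears in a read: the A-tail base plus the stem.
THREE_PRIME_ADAPTOR = "A" + INDEX_ADAPTOR_STEM


@dataclass(frozen=True)
class ReadRecord:
    """One FASTQ record; quality is Phred+33 and in register with the sequence."""

    identifier: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"{self.identifier}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )
        if any(not (33 <= ord(c) <= 126) for c in self.quality):
            raise ValueError(f"{self.identifier}: quality characters outside Phred+33 range")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AdaptorSet:
    five_prime: Tuple[str, ...] = (DAMID_PCR_PRIMER,)
    three_prime: Tuple[str, ...] = (THREE_PRIME_ADAPTOR,)
    max_error_rate: float = 0.1
    min_overlap: int = 3


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _five_prime_cut(seq: str, adaptor: str, rate: float, min_overlap: int) -> int:
    """Longest prefix of *seq* matching a suffix of *adaptor*; 0 if none."""
    for k in range(min(len(adaptor), len(seq)), min_overlap - 1, -1):
        if _mismatches(seq[:k], adaptor[-k:]) <= int(rate * k):
            return k
    return 0


def _three_prime_cut(seq: str, adaptor: str, rate: float, min_overlap: int) -> int:
    """Earliest position where *adaptor* starts in *seq*; len(seq) if absent.

    Full occurrences are allowed anywhere; partial occurrences only at the
    read end (a prefix of the adaptor running off the read).
    """
    n = len(seq)
    for p in range(n - min_overlap + 1):
        overlap = min(len(adaptor), n - p)
        if _mismatches(seq[p : p + overlap], adaptor[:overlap]) <= int(rate * overlap):
            return p
    return n


def trim_read(read: ReadRecord, adaptors: AdaptorSet = AdaptorSet()) -> ReadRecord:
    """Remove 5' primer and 3' adaptor from *read*; qualities stay in register.

    Untrimmable reads pass through unchanged.
    """
    seq, qual = read.sequence, read.quality
    cut5 = max(
        (_five_prime_cut(seq, a, adaptors.max_error_rate, adaptors.min_overlap) for a in adaptors.five_prime),
        default=0,
    )
    seq, qual = seq[cut5:], qual[cut5:]
    cut3 = min(
        (_three_prime_cut(seq, a, adaptors.max_error_rate, adaptors.min_overlap) for a in adaptors.three_prime),
        default=len(seq),
    )
    seq, qual = seq[:cut3], qual[:cut3]
    if seq == read.sequence:
        return read
    return ReadRecord(read.identifier, seq, qual)


def quality_trim_3prime(read: ReadRecord, threshold: int = 20) -> ReadRecord:
    """Optional 3' quality trimming (BWA-style partial-sum), default off in
    the pipeline because the protocol states no Phred threshold."""
    scores = [ord(c) - 33 for c in read.quality]
    best, running, cut = 0, 0, len(read)
    for i in range(len(read) - 1, -1, -1):
        running += threshold - scores[i]
        if running < 0:
            break
        if running > best:
            best, cut = running, i
    if cut == len(read):
        return read
    return ReadRecord(read.identifier, read.sequence[:cut], read.quality[:cut])


@dataclass
class FilterCounts:
    kept: int = 0
    too_short: int = 0
    too_long: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.too_short + self.too_long


def length_filter(
    reads: Iterable[ReadRecord], min_len: int = 30, max_len: int = 50
) -> Tuple[List[ReadRecord], FilterCounts]:
    """Keep reads with ``min_len <= length <= max_len`` (both inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    counts = FilterCounts()
    kept: List[ReadRecord] = []
    for read in reads:
        n = len(read)
        if n < min_len:
            counts.too_short += 1
        elif n > max_len:
            counts.too_long += 1
        else:
            counts.kept += 1
            kept.append(read)
    return kept, counts


# ---------------------------------------------------------------------------
# FASTQ I/O — 4-line records, byte-exact round trips, transparent gzip
# ---------------------------------------------------------------------------

PathLike = Union[str, Path, IO[str]]


def _open_text(path: Union[str, Path], mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(source: PathLike) -> List[ReadRecord]:
    """Parse a FASTQ file (optionally gzipped) into ReadRecords.

    A truncated trailing record raises ``ValueError`` naming the record index.
    """

    def _parse(fh: IO[str]) -> List[ReadRecord]:
        reads: List[ReadRecord] = []
        lines = [ln.rstrip("\n") for ln in fh]
        while lines and lines[-1] == "":
            lines.pop()
        if len(lines) % 4 != 0:
            raise ValueError(
                f"truncated FASTQ record at record index {len(lines) // 4}"
            )
        for i in range(0, len(lines), 4):
            header, seq, plus, qual = lines[i : i + 4]
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record at record index {i // 4}")
            reads.append(ReadRecord(header[1:], seq, qual))
        return reads

    if hasattr(source, "read"):
        return _parse(source)
    with _open_text(source, "r") as fh:
        return _parse(fh)


def write_fastq(reads: Iterable[ReadRecord], sink: PathLike) -> None:
    def _emit(fh: IO[str]) -> None:
        for r in reads:
            fh.write(f"@{r.identifier}\n{r.sequence}\n+\n{r.quality}\n")

    if hasattr(sink, "write"):
        _emit(sink)
    else:
        with _open_text(sink, "w") as fh:
            _emit(fh)


# ---------------------------------------------------------------------------
# Aggregate QC
# ---------------------------------------------------------------------------

def qc_summary(reads: Sequence[ReadRecord]) -> Dict[str, object]:
    """Read count and length histogram for one file."""
    hist: Dict[int, int] = {}
    for r in reads:
        hist[len(r)] = hist.get(len(r), 0) + 1
    return {"n_reads": len(reads), "length_histogram": dict(sorted(hist.items()))}


def write_qc_report(summaries: Dict[str, Dict[str, object]], sink: PathLike) -> None:
    """TSV report: one row per (file, read length) plus per-file totals."""

    def _emit(fh: IO[str]) -> None:
        fh.write("file\tmetric\tvalue\n")
        for name, summ in summaries.items():
            fh.write(f"{name}\tn_reads\t{summ['n_reads']}\n")
            for length, count in summ["length_histogram"].items():  # type: ignore[union-attr]
                fh.write(f"{name}\tlength_{length}\t{count}\n")

    if hasattr(sink, "write"):
        _emit(sink)
    else:
        with open(sink, "w") as fh:
            _emit(fh)
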