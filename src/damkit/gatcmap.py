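"""GATC fragment maps: the coordinate system of DamID signal.

Dam methylase marks adenines in GATC motifs, so the natural resolution unit
of a DamID experiment is the genomic fragment between two consecutive GATC
motifs.  This module tiles a genome into such fragments and serialises the
tiling as GFF3.

Conventions
-----------
* Internal coordinates are 0-based, half-open.
* Fragment boundaries sit at ``motif_start + 2``, i.e. between GA and TC,
  mirroring the blunt cut DpnI makes in a methylated GATC.
* On disk the tiling is GFF3 (1-based, inclusive), source ``gatcmap``,
  feature ``GATC_frag``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Dict, Iterator, List, Tuple, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeSequence",
    "GatcFragmentMap",
    "find_gatc_sites",
    "build_fragment_map",
    "read_fasta",
    "write_fasta",
    "write_gatc_gff",
    "read_gatc_gff",
]

#: A genome is an ordered mapping chromosome name -> uppercase DNA string.
GenomeSequence = Dict[str, str]

_VALID_SEQ = re.compile(r"^[ACGTN]*$")
_MOTIF = "GATC"
#: Offset of the cut site within the motif (between GA and TC).
CUT_OFFSET = 2

PathLike = Union[str, Path, IO[str]]


def _validate_sequence(seq: str) -> None:
    if not _VALID_SEQ.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(
            f"sequence contains characters outside uppercase A/C/G/T/N: {bad!r}"
        )


def find_gatc_sites(seq: str) -> List[int]:
    """Return sorted 0-based start positions of every GATC motif in *seq*.

    The scan is exhaustive (overlapping occurrences are impossible for this
    motif).  ``N`` never matches; lowercase or non-IUPAC characters raise
    ``ValueError``.
    """
    _validate_sequence(seq)
    sites = []
    pos = seq.find(_MOTIF)
    while pos != -1:
        sites.append(pos)
        pos = seq.find(_MOTIF, pos + 1)
    return sites


@dataclass
class GatcFragmentMap:
    """Tiling of each chromosome into GATC-delimited fragments.

    ``fragments[chrom]`` is a sorted list of half-open ``(start, end)``
    intervals that tile ``[0, length)`` exactly.  A chromosome with *k*
    GATC motifs has *k* + 1 fragments (one fragment if it has none).
    """

    fragments: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)
    chrom_lengths: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if set(self.fragments) != set(self.chrom_lengths):
            raise ValueError("fragments and chrom_lengths name different chromosomes")
        for chrom, frags in self.fragments.items():
            length = self.chrom_lengths[chrom]
            if not frags:
                raise ValueError(f"{chrom}: empty fragment list")
            if frags[0][0] != 0 or frags[-1][1] != length:
                raise ValueError(f"{chrom}: fragments do not span [0, {length})")
            for (s0, e0), (s1, e1) in zip(frags, frags[1:]):
                if e0 != s1:
                    raise ValueError(f"{chrom}: gap or overlap at {e0}/{s1}")
            for s, e in frags:
                if s >= e:
                    raise ValueError(f"{chrom}: empty or inverted fragment ({s}, {e})")

    @property
    def chromosomes(self) -> List[str]:
        return list(self.fragments)

    @property
    def n_fragments(self) -> int:
        return sum(len(f) for f in self.fragments.values())

    def iter_fragments(self) -> Iterator[Tuple[str, int, int]]:
        """Yield ``(chrom, start, end)`` in chromosome order, then position."""
        for chrom, frags in self.fragments.items():
            for s, e in frags:
                yield chrom, s, e

    def fragment_lengths(self, chrom: str) -> List[int]:
        return [e - s for s, e in self.fragments[chrom]]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GatcFragmentMap):
            return NotImplemented
        return (
            self.fragments == other.fragments
            and self.chrom_lengths == other.chrom_lengths
        )


def build_fragment_map(genome: GenomeSequence) -> GatcFragmentMap:
    """Tile every chromosome of *genome* into GATC fragments.

    Each internal boundary is ``motif_start + 2`` (the DpnI blunt cut
    between GA and TC); the first fragment starts at 0 and the last ends at
    the chromosome length.
    """
    if not genome:
        raise ValueError("empty genome")
    fragments: Dict[str, List[Tuple[int, int]]] = {}
    lengths: Dict[str, int] = {}
    for chrom, seq in genome.items():
        if not chrom:
            raise ValueError("empty chromosome name")
        if len(seq) < 1:
            raise ValueError(f"{chrom}: empty sequence")
        cuts = [p + CUT_OFFSET for p in find_gatc_sites(seq)]
        bounds = [0] + cuts + [len(seq)]
        # A motif at the very start/end can make a cut coincide with 0 or L;
        # dedupe so the tiling stays strict.
        bounds = sorted(set(bounds))
        fragments[chrom] = list(zip(bounds, bounds[1:]))
        lengths[chrom] = len(seq)
    return GatcFragmentMap(fragments=fragments, chrom_lengths=lengths)


# ---------------------------------------------------------------------------
# FASTA I/O (thin Bio.SeqIO wrappers enforcing the GenomeSequence contract)
# ---------------------------------------------------------------------------

def read_fasta(source: PathLike) -> GenomeSequence:
    """Read a (multi-record, line-wrapped) FASTA into a GenomeSequence."""
    genome: GenomeSequence = {}
    for rec in SeqIO.parse(source, "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate chromosome name {rec.id!r}")
        seq = str(rec.seq).upper()
        _validate_sequence(seq)
        genome[rec.id] = seq
    if not genome:
        raise ValueError("no FASTA records found")
    return genome


def write_fasta(genome: GenomeSequence, sink: PathLike, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    if hasattr(sink, "write"):
        SeqIO.write(records, sink, "fasta")
    else:
        with open(sink, "w") as fh:
            SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# GFF3 serialisation of the fragment map
# ---------------------------------------------------------------------------

_GFF_SOURCE = "gatcmap"
_GFF_FEATURE = "GATC_frag"


def write_gatc_gff(fmap: GatcFragmentMap, sink: PathLike) -> None:
    """Write the fragment map as GFF3 (1-based inclusive coordinates)."""

    def _emit(fh: IO[str]) -> None:
        fh.write("##gff-version 3\n")
        i = 0
        for chrom, start, end in fmap.iter_fragments():
            i += 1
            fh.write(
                f"{chrom}\t{_GFF_SOURCE}\t{_GFF_FEATURE}\t{start + 1}\t{end}\t.\t.\t.\t"
                f"ID=frag{i}\n"
            )

    if hasattr(sink, "write"):
        _emit(sink)
    else:
        with open(sink, "w") as fh:
            _emit(fh)


def read_gatc_gff(source: PathLike) -> GatcFragmentMap:
    """Read a fragment map written by :func:`write_gatc_gff`.

    Raises ``ValueError`` on malformed records (end < start, gaps, overlaps).
    """

    def _parse(fh: IO[str]) -> GatcFragmentMap:
        fragments: Dict[str, List[Tuple[int, int]]] = {}
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"line {lineno}: expected 9 GFF columns, got {len(cols)}")
            chrom, _src, _feat, start_s, end_s = cols[:5]
            start1, end1 = int(start_s), int(end_s)
            if end1 < start1:
                raise ValueError(f"line {lineno}: end {end1} before start {start1}")
            fragments.setdefault(chrom, []).append((start1 - 1, end1))
        if not fragments:
            raise ValueError("no GFF fragment records found")
        lengths = {chrom: frags[-1][1] for chrom, frags in fragments.items()}
        return GatcFragmentMap(fragments=fragments, chrom_lengths=lengths)

    if hasattr(source, "read"):
        return _parse(source)
    with open(source) as fh:
        return _parse(fh)
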