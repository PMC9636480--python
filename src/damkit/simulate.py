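"""Synthetic NanoDam experiments with known ground truth.

The generator emulates the methylation biology a NanoDam/DamID experiment
profiles: Dam methylase deposits adenine methylation at GATC motifs, with
high probability next to fragments bound by the tagged protein (fusion
samples) and low background probability at open chromatin everywhere
(fusion and Dam-only samples alike).  DpnI then cuts between two
*methylated* GATC sites, releasing the intervening fragment; released
fragments are amplified (PCR duplicates), sonicated to ~300 bp and
sequenced as 50 nt single-end reads that optionally carry the DamID PCR
primer at their 5' end.

Everything is driven by a single integer seed; sample ``i`` of an
experiment uses ``seed + 1 + i`` so fixtures are stable and samples are
independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, IO, List, Optional, Tuple, Union

import numpy as np

from .gatcmap import GatcFragmentMap, GenomeSequence, build_fragment_map, find_gatc_sites
from .readprep import ReadRecord

__all__ = [
    "SimConfig",
    "SimTruth",
    "MethylationTally",
    "DAMID_PCR_PRIMER",
    "simulate_genome",
    "simulate_truth",
    "simulate_sample",
    "simulate_experiment",
    "write_truth",
    "read_truth",
]

#: DamID PCR primer that flanks every genomic insert after the DamID PCR.
DAMID_PCR_PRIMER = "GGTCGCGGCCGAGGATC"

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a synthetic NanoDam experiment.

    Defaults follow the assay: ~190 bp GATC spacing (fly-like), 50 nt
    single-end reads, ~300 bp sonication, modest PCR duplication.  The
    methylation rates (``p_bound`` high next to bound fragments, ``p_open``
    low background in open chromatin) are free parameters of the model —
    the assay itself has no published quantitative rate.
    """

    n_chromosomes: int = 1
    chromosome_length: int = 200_000
    mean_gatc_spacing: float = 190.0
    n_binding_sites: int = 40
    p_bound: float = 0.8
    p_open: float = 0.05
    n_molecules: int = 50_000
    pcr_duplicate_mean: float = 1.5
    read_length: int = 50
    sonication_mean: float = 300.0
    include_adaptors: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_open <= self.p_bound <= 1.0):
            raise ValueError("require 0 <= p_open <= p_bound <= 1")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.pcr_duplicate_mean < 1.0:
            raise ValueError("pcr_duplicate_mean must be >= 1")
        if self.mean_gatc_spacing < 5:
            raise ValueError("mean_gatc_spacing must be >= 5")


@dataclass
class MethylationTally:
    """Per-GATC-site methylation bookkeeping for one simulated sample.

    ``site_positions[chrom]`` are the cut coordinates (internal fragment
    boundaries); ``n_methylated[chrom]`` counts methylation events per site
    over ``n_genome_copies`` independently methylated genome copies.
    """

    site_positions: Dict[str, np.ndarray]
    n_methylated: Dict[str, np.ndarray]
    n_genome_copies: int


@dataclass
class SimTruth:
    """Planted binding fragments plus per-sample methylation tallies."""

    fragments: List[Tuple[str, Tuple[int, int]]]
    tallies: Dict[str, MethylationTally] = field(default_factory=dict)

    def validate_against(self, fmap: GatcFragmentMap) -> None:
        for chrom, frag in self.fragments:
            if chrom not in fmap.fragments or frag not in set(fmap.fragments[chrom]):
                raise ValueError(f"truth fragment {chrom}:{frag} not in fragment map")


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def _scrub_accidental_gatc(seq: np.ndarray, planted: np.ndarray) -> None:
    """Mutate away GATC occurrences that were not planted (in place).

    *seq* is a byte array; any unplanned motif has its C replaced by A,
    rescanning until clean (a replacement can only create a new motif in a
    4 bp neighbourhood, so this converges quickly).
    """
    planted_set = set(int(p) for p in planted)
    s = seq.tobytes().decode()
    while True:
        extra = [p for p in find_gatc_sites(s) if p not in planted_set]
        if not extra:
            break
        for p in extra:
            seq[p + 3] = ord("A")
        s = seq.tobytes().decode()


def simulate_genome(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> GenomeSequence:
    """Generate a toy genome with GATC motifs at controlled spacing.

    Inter-motif start spacing is geometric with mean ``cfg.mean_gatc_spacing``
    (floored at 5 bp so motifs never collide); background sequence is random
    with accidental GATC occurrences mutated away, so the planted motifs are
    exactly the motifs present.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if cfg.chromosome_length < cfg.mean_gatc_spacing + 4:
        raise ValueError("chromosome_length too short to place a single GATC motif")
    genome: GenomeSequence = {}
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for c in range(cfg.n_chromosomes):
        length = cfg.chromosome_length
        seq = rng.choice(bases, size=length)
        # motif start positions: cumulative geometric gaps, floored at 5 bp
        n_draw = int(2 * length / cfg.mean_gatc_spacing) + 10
        gaps = np.maximum(rng.geometric(1.0 / cfg.mean_gatc_spacing, size=n_draw), 5)
        starts = np.cumsum(gaps)
        starts = starts[starts + 4 <= length - 1]
        motif = np.frombuffer(b"GATC", dtype=np.uint8)
        for p in starts:
            seq[p : p + 4] = motif
        _scrub_accidental_gatc(seq, starts)
        genome[f"chrSim{c + 1}"] = seq.tobytes().decode()
    return genome


def simulate_truth(
    fmap: GatcFragmentMap, cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> SimTruth:
    """Pick ``cfg.n_binding_sites`` interior fragments as true binding sites."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    candidates = [
        (chrom, frag)
        for chrom, frags in fmap.fragments.items()
        for frag in frags[1:-1]  # interior fragments have two GATC boundaries
    ]
    if cfg.n_binding_sites > len(candidates):
        raise ValueError("not enough interior fragments for requested binding sites")
    idx = rng.choice(len(candidates), size=cfg.n_binding_sites, replace=False)
    chosen = sorted((candidates[i] for i in idx), key=lambda t: (t[0], t[1][0]))
    return SimTruth(fragments=chosen)


# ---------------------------------------------------------------------------
# Samples
# ---------------------------------------------------------------------------

def _cut_positions(fmap: GatcFragmentMap, chrom: str) -> np.ndarray:
    """Internal fragment boundaries == GATC cut sites of *chrom*."""
    frags = fmap.fragments[chrom]
    return np.array([e for _s, e in frags[:-1]], dtype=np.int64)


def simulate_sample(
    genome: GenomeSequence,
    fmap: GatcFragmentMap,
    truth: SimTruth,
    role: str,
    cfg: SimConfig,
    sample_id: str = "sample",
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[ReadRecord], MethylationTally]:
    """Simulate one sequencing library and its methylation tally.

    Genome copies are methylated independently site by site: probability
    ``p_bound`` at sites flanking a truth fragment when ``role == 'fusion'``,
    ``p_open`` everywhere else.  Fragments released between consecutive
    methylated sites are collected until ``cfg.n_molecules`` molecules
    exist; each is sonicated (normal around ``sonication_mean``, sd 15 %,
    truncated at the read length), sequenced from one of its GATC ends on
    the corresponding strand, and PCR-duplicated with a geometric copy
    count of mean ``pcr_duplicate_mean``.
    """
    if role not in ("fusion", "damonly"):
        raise ValueError(f"role must be 'fusion' or 'damonly', got {role!r}")
    truth.validate_against(fmap)
    rng = np.random.default_rng(cfg.seed) if rng is None else rng

    truth_by_chrom: Dict[str, set] = {}
    for chrom, (s, e) in truth.fragments:
        truth_by_chrom.setdefault(chrom, set()).update((s, e))

    site_pos: Dict[str, np.ndarray] = {}
    site_p: Dict[str, np.ndarray] = {}
    for chrom in fmap.chromosomes:
        cuts = _cut_positions(fmap, chrom)
        site_pos[chrom] = cuts
        p = np.full(cuts.shape, cfg.p_open)
        if role == "fusion" and chrom in truth_by_chrom:
            bound = np.isin(cuts, np.fromiter(truth_by_chrom[chrom], dtype=np.int64))
            p[bound] = cfg.p_bound
        site_p[chrom] = p

    # expected released fragments per genome copy, to size the batches
    exp_per_copy = sum(max(float(p.sum()) - 1.0, 0.0) for p in site_p.values())
    molecules: List[Tuple[str, int, int]] = []
    n_meth = {chrom: np.zeros(len(cuts), dtype=np.int64) for chrom, cuts in site_pos.items()}
    n_copies = 0
    max_rounds = 60
    for _round in range(max_rounds):
        if len(molecules) >= cfg.n_molecules:
            break
        deficit = cfg.n_molecules - len(molecules)
        if exp_per_copy > 0:
            batch = max(8, int(1.2 * deficit / exp_per_copy) + 1)
        elif cfg.p_bound == 0.0 and cfg.p_open == 0.0:
            break  # nothing can ever methylate
        else:
            batch = 256
        for chrom in fmap.chromosomes:
            cuts, p = site_pos[chrom], site_p[chrom]
            if len(cuts) < 2:
                continue  # a chromosome with <2 sites never releases a fragment
            meth = rng.random((batch, len(cuts))) < p
            n_meth[chrom] += meth.sum(axis=0)
            for row in meth:
                idx = np.flatnonzero(row)
                for a, b in zip(idx[:-1], idx[1:]):
                    molecules.append((chrom, int(cuts[a]), int(cuts[b])))
        n_copies += batch
    molecules = molecules[: cfg.n_molecules]

    reads: List[ReadRecord] = []
    prefix = DAMID_PCR_PRIMER if cfg.include_adaptors else ""
    sd = 0.15 * cfg.sonication_mean
    for i, (chrom, fs, fe) in enumerate(molecules):
        frag_len = fe - fs
        L = int(round(rng.normal(cfg.sonication_mean, sd)))
        L = min(max(L, cfg.read_length), frag_len)
        left_end = bool(rng.integers(2) == 0)
        if left_end:
            insert = genome[chrom][fs : fs + L]
            strand = "+"
        else:
            insert = reverse_complement(genome[chrom][fe - L : fe])
            strand = "-"
        seq = (prefix + insert)[: cfg.read_length]
        qual = "I" * len(seq)
        n_copies_pcr = int(rng.geometric(1.0 / cfg.pcr_duplicate_mean))
        for j in range(n_copies_pcr):
            rid = f"sim:{sample_id}:mol{i}:{chrom}:{fs}-{fe}:{strand}:dup{j}"
            reads.append(ReadRecord(rid, seq, qual))

    tally = MethylationTally(site_positions=site_pos, n_methylated=n_meth, n_genome_copies=n_copies)
    truth.tallies[sample_id] = tally
    return reads, tally


def simulate_experiment(
    cfg: SimConfig, n_fusion: int = 3, n_damonly: int = 3
) -> Tuple[GenomeSequence, GatcFragmentMap, SimTruth, Dict[str, List[ReadRecord]], Dict[str, str]]:
    """Simulate a full experiment: genome, truth and all sample libraries.

    Returns ``(genome, fmap, truth, reads_by_id, roles_by_id)``.  Sample
    ``i`` (0-based, fusion samples first) draws from ``cfg.seed + 1 + i``.
    """
    genome = simulate_genome(cfg)
    fmap = build_fragment_map(genome)
    truth = simulate_truth(fmap, cfg)
    reads_by_id: Dict[str, List[ReadRecord]] = {}
    roles: Dict[str, str] = {}
    sample_specs = [(f"fusion_R{i + 1}", "fusion") for i in range(n_fusion)] + [
        (f"damonly_R{i + 1}", "damonly") for i in range(n_damonly)
    ]
    for i, (sid, role) in enumerate(sample_specs):
        rng = np.random.default_rng(cfg.seed + 1 + i)
        reads, _ = simulate_sample(genome, fmap, truth, role, cfg, sample_id=sid, rng=rng)
        reads_by_id[sid] = reads
        roles[sid] = role
    return genome, fmap, truth, reads_by_id, roles


# ---------------------------------------------------------------------------
# Truth I/O (BED6)
# ---------------------------------------------------------------------------

PathLike = Union[str, Path, IO[str]]


def write_truth(truth: SimTruth, sink: PathLike) -> None:
    """Write true binding fragments as BED6 (0-based half-open)."""

    def _emit(fh: IO[str]) -> None:
        for i, (chrom, (s, e)) in enumerate(truth.fragments, 1):
            fh.write(f"{chrom}\t{s}\t{e}\ttruth_{i}\t0\t.\n")

    if hasattr(sink, "write"):
        _emit(sink)
    else:
        with open(sink, "w") as fh:
            _emit(fh)


def read_truth(source: PathLike) -> SimTruth:
    def _parse(fh: IO[str]) -> SimTruth:
        frags = []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"BED line with <3 columns: {line!r}")
            frags.append((cols[0], (int(cols[1]), int(cols[2]))))
        return SimTruth(fragments=frags)

    if hasattr(source, "read"):
        return _parse(source)
    with open(source) as fh:
        return _parse(fh)
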