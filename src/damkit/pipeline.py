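"""End-to-end orchestration: reads to tracks, peaks and QC.

`run_analysis` is the in-memory engine: trim -> align -> count -> pairwise
ratio tracks -> quantile-normalize -> average -> broad peaks -> FDR
consensus -> reproducible set -> QC.  `run_pipeline` wraps it with file
I/O and reproduces the conventional output layout: one ``<exp>_vs_<ctrl>``
directory per pairwise comparison plus ``<prefix>_tracks``,
``<prefix>_DamOnly_tracks``, ``<prefix>_peaks`` and
``<prefix>_DamOnly_peaks`` folders, with a JSON run log recording every
parameter and input checksum.  Re-running an identical configuration
produces byte-identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from . import __version__
from .counts import (
    Alignment,
    AlignStats,
    FragmentCounts,
    GenomeIndex,
    align_exact,
    bin_coverage,
    count_fragments,
    read_sam,
)
from .gatcmap import GatcFragmentMap, GenomeSequence, build_fragment_map, read_fasta, write_gatc_gff
from .grid import ComparisonGrid, build_grid
from .peaks import (
    ConsensusConfig,
    PeakCallParams,
    PeakSet,
    call_broad_peaks,
    reproducible_peaks,
    threshold_consensus,
    write_broadpeak,
)
from .qc import (
    QcThresholds,
    complexity_curve,
    correlation_matrix,
    enrichment_profile,
    fingerprint_curve,
    flag_libraries,
)
from .readprep import AdaptorSet, ReadRecord, length_filter, read_fastq, trim_read
from .tracks import (
    RatioParams,
    ScoredTrack,
    average_tracks,
    damonly_track,
    quantile_normalize,
    ratio_track,
    track_from_binned,
    write_bedgraph,
)

__all__ = ["PipelineConfig", "AnalysisResult", "run_analysis", "run_pipeline"]


@dataclass
class SampleSpec:
    sample_id: str
    role: str  # 'fusion' | 'damonly'
    fastq: Optional[Path] = None
    sam: Optional[Path] = None


@dataclass
class PipelineConfig:
    genome_fasta: Path
    samples: List[SampleSpec]
    output_root: Path
    prefix: str = "nanodam"
    min_length: int = 30
    max_length: int = 50
    extension: int = 300
    bin_size: int = 500
    bin_extension: int = 150
    ratio_params: RatioParams = field(default_factory=RatioParams)
    peak_params: PeakCallParams = field(default_factory=PeakCallParams)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    qc_thresholds: QcThresholds = field(default_factory=QcThresholds)
    repro_threshold: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.genome_fasta).exists():
            raise FileNotFoundError(f"genome FASTA not found: {self.genome_fasta}")
        roles = {s.role for s in self.samples}
        if not roles <= {"fusion", "damonly"}:
            raise ValueError(f"unknown sample roles: {sorted(roles - {'fusion', 'damonly'})}")
        if not any(s.role == "fusion" for s in self.samples) or not any(
            s.role == "damonly" for s in self.samples
        ):
            raise ValueError("need at least one fusion and one damonly sample")
        for s in self.samples:
            src = s.fastq or s.sam
            if src is None or not Path(src).exists():
                raise FileNotFoundError(f"sample {s.sample_id}: input not found: {src}")


@dataclass
class AnalysisResult:
    fmap: GatcFragmentMap
    counts_by_id: Dict[str, FragmentCounts]
    align_stats: Dict[str, AlignStats]
    grid: ComparisonGrid
    pair_ratio_tracks: Dict[str, ScoredTrack]
    qnorm_tracks: Dict[str, ScoredTrack]
    averaged_track: ScoredTrack
    damonly_tracks: Dict[str, ScoredTrack]
    averaged_damonly_track: ScoredTrack
    pair_peaks: Dict[str, PeakSet]
    consensus_by_threshold: Dict[float, PeakSet]
    repro_peaks: PeakSet
    binned_tracks: Dict[str, ScoredTrack]
    correlation: "object"  # pandas DataFrame
    library_flags: "object"
    fingerprints: Dict[str, "object"]
    alignments_by_id: Dict[str, List[Alignment]]


def _prepare_reads(
    reads: Sequence[ReadRecord],
    adaptors: AdaptorSet,
    min_length: int,
    max_length: int,
) -> List[ReadRecord]:
    trimmed = [trim_read(r, adaptors) for r in reads]
    kept, _counts = length_filter(trimmed, min_length, max_length)
    return kept


def run_analysis(
    genome: GenomeSequence,
    reads_by_id: Dict[str, Sequence[ReadRecord]],
    roles: Dict[str, str],
    *,
    adaptors: AdaptorSet = AdaptorSet(),
    min_length: int = 30,
    max_length: int = 50,
    extension: int = 300,
    bin_size: int = 500,
    bin_extension: int = 150,
    ratio_params: RatioParams = RatioParams(),
    peak_params: PeakCallParams = PeakCallParams(),
    consensus: ConsensusConfig = ConsensusConfig(),
    qc_thresholds: QcThresholds = QcThresholds(),
    repro_threshold: float = 10.0,
    alignments_by_id: Optional[Dict[str, List[Alignment]]] = None,
) -> AnalysisResult:
    """Run the full analysis in memory and return every intermediate.

    ``alignments_by_id`` may pre-supply alignments (e.g. from SAM files),
    bypassing trimming and the exact aligner for those samples.
    """
    fmap = build_fragment_map(genome)
    fusion_ids = [s for s, r in roles.items() if r == "fusion"]
    damonly_ids = [s for s, r in roles.items() if r == "damonly"]

    index = GenomeIndex(genome)
    aligned: Dict[str, List[Alignment]] = {}
    stats: Dict[str, AlignStats] = {}
    for sid in roles:
        if alignments_by_id is not None and sid in alignments_by_id:
            aligned[sid] = alignments_by_id[sid]
            stats[sid] = AlignStats(aligned=len(aligned[sid]))
        else:
            prepped = _prepare_reads(reads_by_id[sid], adaptors, min_length, max_length)
            aligned[sid], stats[sid] = align_exact(prepped, index)

    counts_by_id = {
        sid: count_fragments(alns, fmap, extension=extension) for sid, alns in aligned.items()
    }

    grid = build_grid(fusion_ids, damonly_ids)
    pair_tracks = {
        name: ratio_track(counts_by_id[e], counts_by_id[c], ratio_params, label=name)
        for (e, c), name in zip(grid.pairs, grid.names)
    }
    qnormed = dict(zip(pair_tracks, quantile_normalize(list(pair_tracks.values()))))
    averaged = average_tracks(list(qnormed.values()), label="averaged")

    damonly_raw = {sid: damonly_track(counts_by_id[sid], label=sid) for sid in damonly_ids}
    damonly_q = dict(zip(damonly_raw, quantile_normalize(list(damonly_raw.values()))))
    averaged_damonly = average_tracks(list(damonly_q.values()), label="averaged_damonly")

    pair_peaks = {
        name: call_broad_peaks(counts_by_id[e], counts_by_id[c], peak_params, name_prefix=name)
        for (e, c), name in zip(grid.pairs, grid.names)
    }
    consensus_sets = threshold_consensus(pair_peaks, consensus)
    repro = reproducible_peaks(pair_peaks, consensus, at_threshold=repro_threshold)

    chrom_sizes = fmap.chrom_lengths
    binned = {
        sid: track_from_binned(
            bin_coverage(alns, chrom_sizes, bin_size=bin_size, extension=bin_extension), label=sid
        )
        for sid, alns in aligned.items()
    }
    corr = correlation_matrix(binned)
    flags = flag_libraries(corr, dict(roles), qc_thresholds)
    fingerprints = {
        sid: fingerprint_curve(binned[sid].flat_values()) for sid in roles
    }

    return AnalysisResult(
        fmap=fmap,
        counts_by_id=counts_by_id,
        align_stats=stats,
        grid=grid,
        pair_ratio_tracks=pair_tracks,
        qnorm_tracks=qnormed,
        averaged_track=averaged,
        damonly_tracks=damonly_q,
        averaged_damonly_track=averaged_damonly,
        pair_peaks=pair_peaks,
        consensus_by_threshold=consensus_sets,
        repro_peaks=repro,
        binned_tracks=binned,
        correlation=corr,
        library_flags=flags,
        fingerprints=fingerprints,
        alignments_by_id=aligned,
    )


# ---------------------------------------------------------------------------
# File-based pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> AnalysisResult:
    """Execute the whole pipeline on files and write the output tree.

    Raises before writing anything if the configuration is invalid; the
    same configuration always produces byte-identical output.
    """
    config.validate()
    genome = read_fasta(config.genome_fasta)
    reads_by_id: Dict[str, Sequence[ReadRecord]] = {}
    pre_aligned: Dict[str, List[Alignment]] = {}
    roles: Dict[str, str] = {}
    checksums: Dict[str, str] = {str(config.genome_fasta): _sha256(Path(config.genome_fasta))}
    for spec in config.samples:
        roles[spec.sample_id] = spec.role
        if spec.sam is not None:
            pre_aligned[spec.sample_id] = read_sam(spec.sam)
            reads_by_id[spec.sample_id] = []
            checksums[str(spec.sam)] = _sha256(Path(spec.sam))
        else:
            reads_by_id[spec.sample_id] = read_fastq(spec.fastq)
            checksums[str(spec.fastq)] = _sha256(Path(spec.fastq))

    result = run_analysis(
        genome,
        reads_by_id,
        roles,
        min_length=config.min_length,
        max_length=config.max_length,
        extension=config.extension,
        bin_size=config.bin_size,
        bin_extension=config.bin_extension,
        ratio_params=config.ratio_params,
        peak_params=config.peak_params,
        consensus=config.consensus,
        qc_thresholds=config.qc_thresholds,
        repro_threshold=config.repro_threshold,
        alignments_by_id=pre_aligned or None,
    )

    root = Path(config.output_root)
    if root.exists():
        shutil.rmtree(root)
    root.mkdir(parents=True)

    write_gatc_gff(result.fmap, root / "gatc_fragments.gff")

    # per-pair directories
    for name in result.grid.names:
        pair_dir = root / name
        pair_dir.mkdir()
        write_bedgraph(result.pair_ratio_tracks[name], pair_dir / f"{name}.ratio.bedgraph")
        write_broadpeak(result.pair_peaks[name], pair_dir / f"{name}.broadPeak")

    tracks_dir = root / f"{config.prefix}_tracks"
    tracks_dir.mkdir()
    for name, track in result.qnorm_tracks.items():
        write_bedgraph(track, tracks_dir / f"{name}.qnorm.bedgraph")
    write_bedgraph(result.averaged_track, tracks_dir / f"{config.prefix}.averaged.bedgraph")

    damonly_dir = root / f"{config.prefix}_DamOnly_tracks"
    damonly_dir.mkdir()
    for sid, track in result.damonly_tracks.items():
        write_bedgraph(track, damonly_dir / f"{sid}.qnorm.bedgraph")
    write_bedgraph(
        result.averaged_damonly_track, damonly_dir / f"{config.prefix}.DamOnly.averaged.bedgraph"
    )

    peaks_dir = root / f"{config.prefix}_peaks"
    peaks_dir.mkdir()
    for name, ps in result.pair_peaks.items():
        write_broadpeak(ps, peaks_dir / f"{name}.broadPeak")
    for fdr, ps in result.consensus_by_threshold.items():
        write_broadpeak(ps, peaks_dir / f"{config.prefix}.FDR{fdr:g}.mergePeak")
    write_broadpeak(
        result.repro_peaks, peaks_dir / f"{config.prefix}.FDR{config.repro_threshold:g}.reproPeak"
    )

    # Dam-only negative-control comparisons (control-vs-control, self excluded)
    damonly_ids = [s.sample_id for s in config.samples if s.role == "damonly"]
    damonly_peaks_dir = root / f"{config.prefix}_DamOnly_peaks"
    damonly_peaks_dir.mkdir()
    if len(damonly_ids) >= 2:
        neg_grid = build_grid(damonly_ids, damonly_ids, exclude_self=True)
        for (e, c), name in zip(neg_grid.pairs, neg_grid.names):
            ps = call_broad_peaks(
                result.counts_by_id[e], result.counts_by_id[c], config.peak_params, name_prefix=name
            )
            write_broadpeak(ps, damonly_peaks_dir / f"{name}.broadPeak")

    result.correlation.to_csv(root / "qc_correlation.tsv", sep="\t")
    result.library_flags.to_csv(root / "qc_library_flags.tsv", sep="\t", index=False)

    log = {
        "version": __version__,
        "seed": config.seed,
        "prefix": config.prefix,
        "samples": {s.sample_id: s.role for s in config.samples},
        "parameters": {
            "min_length": config.min_length,
            "max_length": config.max_length,
            "extension": config.extension,
            "bin_size": config.bin_size,
            "bin_extension": config.bin_extension,
            "pseudocount": config.ratio_params.pseudocount,
            "significant_q": config.peak_params.significant_q,
            "linking_q": config.peak_params.linking_q,
            "background_windows": list(config.peak_params.background_windows),
            "fdr_thresholds": list(config.consensus.fdr_thresholds),
            "reproducible_fraction": config.consensus.reproducible_fraction,
            "repro_threshold": config.repro_threshold,
            "qc_within_type": config.qc_thresholds.within_type,
            "qc_pairwise": config.qc_thresholds.pairwise_comparison,
        },
        "input_checksums": checksums,
        "align_stats": {
            sid: dataclasses.asdict(st) for sid, st in result.align_stats.items()
        },
    }
    (root / "run.log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return result
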