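"""End-to-end orchestration of the four detection steps.

extraction -> orphan assembly -> barcode recruitment / reassembly ->
placement. Each stage logs attrition counters into a JSON run report
and caches its main intermediate in the work directory; present caches
are reused so interrupted runs resume. The detection path is fully
deterministic -- randomness exists only in simulation and downsampling.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

from ._dna import revcomp
from .barcode_recruitment import (
    BarcodeList,
    RecruitmentParams,
    build_barcode_lists,
    fetch_reads_by_barcodes,
    reassemble_and_match,
)
from .dbg_assembler import AssemblyParams, Contig, assemble, write_contigs_fasta
from .insertion_placement import (
    InsertionCall,
    PlacementParams,
    best_alignment_subset,
    call_insertions,
    chain_strand,
    dedupe_calls,
    filter_and_emit,
    write_secondary_tsv,
)
from .io_formats import read_fasta_dict, write_vcf
from .pairwise_align import AlignParams, TargetIndex, seed_and_extend
from .read_extraction import (
    ExtractedPair,
    ExtractionThresholds,
    UnalignedSet,
    extract_unaligned_set,
    write_unaligned_fastq,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    bam: Path
    reference: Path
    workdir: Path
    output_vcf: Path
    secondary_out: Optional[Path] = None
    extraction: ExtractionThresholds = field(default_factory=ExtractionThresholds)
    orphan_assembly: AssemblyParams = field(
        default_factory=lambda: AssemblyParams(k=31, coverage_cutoff=3, min_contig_length=200)
    )
    reassembly: AssemblyParams = field(
        default_factory=lambda: AssemblyParams(k=77, coverage_cutoff=3, min_contig_length=200)
    )
    recruitment: RecruitmentParams = field(default_factory=RecruitmentParams)
    placement: PlacementParams = field(default_factory=PlacementParams)
    align: AlignParams = field(default_factory=AlignParams)
    barcode_tag: str = "BX"
    #: optional orphan-contig filter (e.g. external contamination screen)
    contamination_filter: Optional[Callable[[list[Contig]], list[Contig]]] = None
    resume: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.bam = Path(self.bam)
        self.reference = Path(self.reference)
        self.workdir = Path(self.workdir)
        self.output_vcf = Path(self.output_vcf)
        if self.secondary_out is None:
            self.secondary_out = self.output_vcf.with_suffix(".secondary.tsv")
        self.secondary_out = Path(self.secondary_out)


@dataclass
class RunReport:
    counts: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    output_vcf: Optional[str] = None
    secondary_out: Optional[str] = None

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "counts": self.counts,
                    "timings_sec": self.timings,
                    "output_vcf": self.output_vcf,
                    "secondary_out": self.secondary_out,
                },
                fh,
                indent=2,
            )


def _load_uset_cache(workdir: Path) -> Optional[UnalignedSet]:
    p1 = workdir / "unaligned_1.fastq"
    p2 = workdir / "unaligned_2.fastq"
    summary = workdir / "unaligned_summary.json"
    if not (p1.exists() and p2.exists() and summary.exists()):
        return None
    from .io_formats import read_fastx

    with open(summary) as fh:
        meta = json.load(fh)
    uset = UnalignedSet(
        counts=meta["counts"],
        n_pairs_seen=meta["n_pairs_seen"],
        n_unpaired_dropped=meta["n_unpaired_dropped"],
    )
    for r1, r2 in zip(read_fastx(p1), read_fastx(p2)):
        uset.pairs.append(
            ExtractedPair(
                read_id=r1.id,
                barcode=r1.barcode,
                seq1=r1.sequence,
                seq2=r2.sequence,
                qual1=bytes(r1.qualities or []),
                qual2=bytes(r2.qualities or []),
                reason="cached",
            )
        )
    return uset


def run(config: PipelineConfig) -> RunReport:
    """Execute the full pipeline; empty intermediates yield a valid empty VCF."""
    config.workdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        output_vcf=str(config.output_vcf), secondary_out=str(config.secondary_out)
    )
    reference = {k: v.upper() for k, v in read_fasta_dict(config.reference).items()}

    # ---- step 0: extraction of U -----------------------------------------
    t0 = time.perf_counter()
    uset = _load_uset_cache(config.workdir) if config.resume else None
    if uset is None:
        uset = extract_unaligned_set(config.bam, config.extraction, config.barcode_tag)
        write_unaligned_fastq(uset, config.workdir / "unaligned", config.barcode_tag)
    report.counts["n_pairs_seen"] = uset.n_pairs_seen
    report.counts["n_u_pairs"] = len(uset)
    report.timings["extraction"] = round(time.perf_counter() - t0, 2)
    log.info("|U| = %d pairs out of %d", len(uset), uset.n_pairs_seen)

    # ---- step 1: orphan contig assembly ----------------------------------
    t0 = time.perf_counter()
    orphans_fa = config.workdir / "orphans.fasta"
    if config.resume and orphans_fa.exists():
        orphans = [
            Contig(rid, seq, 0.0) for rid, seq in read_fasta_dict(orphans_fa).items()
        ]
    else:
        reads = [s for p in uset.pairs for s in (p.seq1, p.seq2) if s]
        orphans = assemble(reads, config.orphan_assembly)
        if config.contamination_filter is not None:
            orphans = config.contamination_filter(orphans)
        write_contigs_fasta(orphans, orphans_fa)
    report.counts["n_orphans"] = len(orphans)
    report.timings["orphan_assembly"] = round(time.perf_counter() - t0, 2)
    log.info("%d orphan contigs", len(orphans))

    # ---- step 2: barcode list extraction ---------------------------------
    t0 = time.perf_counter()
    blists, _rsets = build_barcode_lists(
        orphans, uset, config.recruitment, config.align
    )
    _write_barcode_tsv(blists, config.workdir / "barcode_lists.tsv")
    report.counts["n_orphans_retained"] = len(blists)
    report.timings["barcode_lists"] = round(time.perf_counter() - t0, 2)
    log.info("%d orphans pass the t >= %d barcode gate", len(blists), config.recruitment.min_barcodes)

    # ---- step 3: reassembly per barcode pool -----------------------------
    t0 = time.perf_counter()
    orphan_by_id = {c.id: c for c in orphans}
    reassembled: list[Contig] = []
    if blists:
        pools = fetch_reads_by_barcodes(config.bam, blists, config.barcode_tag)
        for cid in sorted(blists):
            contig = reassemble_and_match(
                pools[cid],
                orphan_by_id[cid],
                config.reassembly,
                config.align,
                config.recruitment,
            )
            if contig is not None:
                # keep the orphan's id so calls stay traceable to B(c)
                reassembled.append(Contig(cid, contig.sequence, contig.mean_kmer_coverage))
            pools[cid] = []  # release pool memory as we go
    write_contigs_fasta(reassembled, config.workdir / "reassembled.fasta")
    report.counts["n_reassembled"] = len(reassembled)
    report.timings["reassembly"] = round(time.perf_counter() - t0, 2)
    log.info("%d reassembled contigs matched their orphan", len(reassembled))

    # ---- step 4: placement on the reference ------------------------------
    t0 = time.perf_counter()
    calls: list[InsertionCall] = []
    n_placed = 0
    if reassembled:
        ref_index = TargetIndex(reference, config.align)
        for contig in reassembled:
            seq = contig.sequence
            alns = seed_and_extend(contig.id, seq, ref_index, config.align)
            chain = best_alignment_subset(alns)
            if chain and chain_strand(chain) == "-":
                seq = revcomp(seq)
                alns = seed_and_extend(contig.id, seq, ref_index, config.align)
                chain = best_alignment_subset(alns)
            if not chain:
                continue
            contig_calls = call_insertions(chain, contig.id, seq, config.placement)
            if contig_calls:
                n_placed += 1
                calls.extend(contig_calls)
    calls = dedupe_calls(calls)
    primary, secondary = filter_and_emit(calls, reference, config.placement)
    write_vcf(primary, reference, config.output_vcf)
    write_secondary_tsv(secondary, config.secondary_out)
    report.counts["n_placed_contigs"] = n_placed
    report.counts["n_calls"] = len(calls)
    report.counts["n_emitted"] = len(primary)
    report.counts["n_secondary"] = len(secondary)
    report.timings["placement"] = round(time.perf_counter() - t0, 2)
    report.save(config.workdir / "run_report.json")
    log.info("%d VCF calls, %d secondary", len(primary), len(secondary))
    return report


def _write_barcode_tsv(blists: dict[str, BarcodeList], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tn_barcodes\tbarcodes\n")
        for cid in sorted(blists):
            bl = blists[cid]
            fh.write(f"{cid}\t{len(bl)}\t{','.join(sorted(bl.barcodes))}\n")


def read_barcode_tsv(path: Path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            cid, _n, barcodes = line.rstrip("\n").split("\t")
            out[cid] = set(barcodes.split(",")) if barcodes else set()
    return out
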