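"""Barcode list extraction and per-barcode-pool reassembly.

For each orphan contig c, the reads of U are aligned back to c; the
surviving alignments form R(c) and the barcodes seen in R(c) form
B(c). Contigs recruiting fewer than t barcodes are discarded. All
read pairs in the original alignment file carrying a barcode from B(c)
-- aligned or not -- are then pooled and reassembled, and the
reassembled contig best matching the orphan carries the insertion with
its anchors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pysam

from .dbg_assembler import AssemblyParams, Contig, assemble
from .pairwise_align import (
    AlignParams,
    LocalAlignment,
    TargetIndex,
    seed_and_extend,
    seed_and_extend_batch,
)
from .read_extraction import UnalignedSet

log = logging.getLogger(__name__)


@dataclass
class RecruitmentParams:
    min_barcodes: int = 5  # the t parameter
    max_clip_fraction: float = 0.20  # inclusive drop: >= 20% clipped is out
    min_proxy_mapq: int = 1  # requires a unique best chain
    min_match_identity: float = 0.95
    min_orphan_cover: float = 0.50

    def __post_init__(self) -> None:
        if self.min_barcodes < 1:
            raise ValueError("t must be >= 1")


@dataclass
class RecruitedReadSet:
    """R(c): filtered read alignments of U onto one orphan contig."""

    contig_id: str
    read_ids: list[str] = field(default_factory=list)
    barcodes: list[Optional[str]] = field(default_factory=list)  # parallel to read_ids


@dataclass
class BarcodeList:
    """B(c): the set of barcodes observed in R(c)."""

    contig_id: str
    barcodes: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.barcodes)


def filter_contig_alignment(
    aln: LocalAlignment, query_length: int, params: RecruitmentParams
) -> bool:
    """Keep a read-to-contig alignment?

    The clipped fraction is the unaligned share of the query (soft and
    hard clips both count at this stage); exactly 20% clipped is
    dropped. Ambiguous placements (proxy MAPQ below threshold) are
    dropped too.
    """
    clipped = (query_length - aln.query_span) / query_length
    if clipped >= params.max_clip_fraction:
        return False
    return aln.proxy_mapq >= params.min_proxy_mapq


def build_barcode_lists(
    orphans: list[Contig],
    uset: UnalignedSet,
    params: Optional[RecruitmentParams] = None,
    align_params: Optional[AlignParams] = None,
) -> tuple[dict[str, BarcodeList], dict[str, RecruitedReadSet]]:
    """Align U back to the orphan contigs and collect B(c) per contig.

    Returns (barcode lists, R(c)) restricted to contigs recruiting at
    least t barcodes. Reads without a barcode count in R(c) but cannot
    contribute to B(c).
    """
    params = params or RecruitmentParams()
    align_params = align_params or AlignParams()
    if not orphans:
        return {}, {}
    index = TargetIndex({c.id: c.sequence for c in orphans}, align_params)
    rsets: dict[str, RecruitedReadSet] = {c.id: RecruitedReadSet(c.id) for c in orphans}
    mates = [
        (f"{pair.read_id}/{mate}", seq, pair.barcode)
        for pair in uset.pairs
        for mate, seq in ((1, pair.seq1), (2, pair.seq2))
        if seq
    ]
    chunk = 20_000
    for start in range(0, len(mates), chunk):
        batch = mates[start : start + chunk]
        results = seed_and_extend_batch([(qid, seq) for qid, seq, _ in batch], index, align_params)
        for qid, seq, barcode in batch:
            hit_contigs = set()
            for aln in results[qid]:
                if aln.target_id in hit_contigs:
                    continue  # best alignment per contig only
                if filter_contig_alignment(aln, len(seq), params):
                    hit_contigs.add(aln.target_id)
                    rset = rsets[aln.target_id]
                    rset.read_ids.append(qid)
                    rset.barcodes.append(barcode)
    blists: dict[str, BarcodeList] = {}
    kept_rsets: dict[str, RecruitedReadSet] = {}
    for cid, rset in rsets.items():
        barcodes = {b for b in rset.barcodes if b is not None}
        if len(barcodes) < params.min_barcodes:
            continue
        blists[cid] = BarcodeList(cid, barcodes)
        kept_rsets[cid] = rset
    return blists, kept_rsets


def fetch_reads_by_barcodes(
    bam_path: str | Path,
    barcode_lists: dict[str, BarcodeList],
    barcode_tag: str = "BX",
) -> dict[str, list[str]]:
    """One streaming pass pooling read sequences per contig via barcodes.

    Every primary record (mapped or not) whose barcode belongs to B(c)
    lands in c's pool; a barcode shared by several contigs feeds each
    of their pools. Result is independent of the BAM sort order (pools
    are sequence multisets consumed by assembly).
    """
    for cid, bl in barcode_lists.items():
        if not bl.barcodes:
            raise ValueError(f"contig {cid} has an empty barcode list")
    inverted: dict[str, list[str]] = {}
    for cid, bl in barcode_lists.items():
        for bc in bl.barcodes:
            inverted.setdefault(bc, []).append(cid)
    pools: dict[str, list[str]] = {cid: [] for cid in barcode_lists}
    mode = "rb" if str(bam_path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(bam_path), mode, check_sq=False) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                continue
            try:
                cids = inverted.get(rec.get_tag(barcode_tag))
            except KeyError:
                continue
            if not cids:
                continue
            seq = rec.query_sequence
            if not seq:
                continue
            for cid in cids:
                pools[cid].append(seq)
    return pools


def reassemble_and_match(
    pool: list[str],
    orphan: Contig,
    assembly_params: Optional[AssemblyParams] = None,
    align_params: Optional[AlignParams] = None,
    params: Optional[RecruitmentParams] = None,
) -> Optional[Contig]:
    """Reassemble a barcode pool and return the contig matching the orphan.

    The pool is assembled with the reassembly parameters (k=77,
    coverage cutoff 3 by default); each resulting contig is aligned to
    the orphan and the highest-scoring one wins (ties: longer contig,
    then id). Returns None unless some contig covers >= half the
    orphan at >= 95% identity.
    """
    if not pool:
        raise ValueError("empty read pool")
    assembly_params = assembly_params or AssemblyParams(k=77, coverage_cutoff=3)
    align_params = align_params or AlignParams()
    params = params or RecruitmentParams()
    contigs = assemble(pool, assembly_params)
    if not contigs:
        log.info("pool for %s assembled into nothing", orphan.id)
        return None
    index = TargetIndex({"orphan": orphan.sequence}, align_params)
    best: Optional[tuple] = None
    for contig in contigs:
        alns = seed_and_extend(contig.id, contig.sequence, index, align_params)
        for aln in alns:
            if aln.identity < params.min_match_identity:
                continue
            if aln.target_span < params.min_orphan_cover * len(orphan.sequence):
                continue
            key = (-aln.score, -len(contig.sequence), contig.id)
            if best is None or key < best[0]:
                best = (key, contig)
            break  # alignments sorted by score; first qualifying is the contig's best
    return best[1] if best else None
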