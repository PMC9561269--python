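"""Pre-processing filter building the poorly-aligned read-pair set U.

A read pair enters U when at least one mate is unmapped, has mapping
quality below ``min_mapq``, or has more than ``max_clip_fraction``
soft-clipped bases -- provided the pair's average base quality exceeds
``min_mean_base_quality``. U is the only input of orphan-contig
assembly, so the filter is deliberately conservative.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pysam

from .io_formats import DEFAULT_BARCODE_TAG, AlignedRead, SequenceRecord, write_fastx

log = logging.getLogger(__name__)

# pysam numeric opcodes
_OP_M, _OP_I, _OP_S, _OP_H, _OP_EQ, _OP_X = 0, 1, 4, 5, 7, 8
_QUERY_OPS_NUM = {_OP_M, _OP_I, _OP_S, _OP_EQ, _OP_X}

KEEP_REASONS = ("unmapped_end", "low_mapq", "clipped")
DROP_REASONS = ("well_aligned", "low_base_quality")


@dataclass
class ExtractionThresholds:
    min_mapq: int = 10
    max_clip_fraction: float = 0.20
    min_mean_base_quality: float = 20.0
    #: "pooled": one mean over both mates; "per_mate": each mate must pass.
    quality_mode: str = "pooled"

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_clip_fraction <= 1.0:
            raise ValueError("max_clip_fraction must be in [0, 1]")
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")
        if self.quality_mode not in ("pooled", "per_mate"):
            raise ValueError("quality_mode must be 'pooled' or 'per_mate'")


@dataclass(slots=True)
class ExtractedPair:
    """Slim storage form of one retained pair (sequences as aligned-strand)."""

    read_id: str
    barcode: Optional[str]
    seq1: str
    seq2: str
    qual1: bytes
    qual2: bytes
    reason: str


@dataclass
class UnalignedSet:
    """The set U: retained pairs plus per-reason accounting."""

    pairs: list[ExtractedPair] = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    n_pairs_seen: int = 0
    n_unpaired_dropped: int = 0

    def __len__(self) -> int:
        return len(self.pairs)


def clip_fraction(read: AlignedRead) -> float:
    """Soft-clipped fraction of the full query length.

    Hard-clipped bases count in the denominator but not the numerator:
    only soft clips are evidence here (the recruitment stage counts
    both). Unmapped reads return 0.
    """
    if not read.is_mapped or not read.cigar:
        return 0.0
    soft = sum(n for op, n in read.cigar if op == "S")
    total = sum(n for op, n in read.cigar if op in "MIS=XH")
    return soft / total if total else 0.0


def mean_base_quality(pair: tuple[AlignedRead, AlignedRead]) -> Optional[float]:
    """Arithmetic mean Phred quality pooled over both mates (None if absent)."""
    quals = list(pair[0].qualities) + list(pair[1].qualities)
    if not quals:
        return None
    return float(sum(quals)) / len(quals)


def _decide(
    unmapped1: bool,
    mapq1: int,
    clip1: float,
    unmapped2: bool,
    mapq2: int,
    clip2: float,
    thresholds: ExtractionThresholds,
) -> tuple[bool, str]:
    """Alignment-state clause of the filter (quality handled separately)."""
    if unmapped1 or unmapped2:
        return True, "unmapped_end"
    if mapq1 < thresholds.min_mapq or mapq2 < thresholds.min_mapq:
        return True, "low_mapq"
    if clip1 > thresholds.max_clip_fraction or clip2 > thresholds.max_clip_fraction:
        return True, "clipped"
    return False, "well_aligned"


def classify_pair(
    pair: tuple[AlignedRead, AlignedRead], thresholds: ExtractionThresholds
) -> tuple[bool, str]:
    """Keep/drop decision for one mate pair with a reason code.

    Keep iff [some mate unmapped OR mapq < min_mapq OR soft-clip
    fraction > max_clip_fraction] AND mean base quality > threshold.
    """
    r1, r2 = pair
    keep, reason = _decide(
        not r1.is_mapped,
        r1.mapq,
        clip_fraction(r1),
        not r2.is_mapped,
        r2.mapq,
        clip_fraction(r2),
        thresholds,
    )
    if not keep:
        return False, reason
    if thresholds.quality_mode == "per_mate":
        means = [mean_base_quality((r, r)) for r in pair]
        ok = all(m is not None and m > thresholds.min_mean_base_quality for m in means)
    else:
        mean = mean_base_quality(pair)
        ok = mean is not None and mean > thresholds.min_mean_base_quality
    if not ok:
        return False, "low_base_quality"
    return True, reason


def _clip_stats(cigartuples) -> float:
    if not cigartuples:
        return 0.0
    soft = 0
    total = 0
    for op, n in cigartuples:
        if op == _OP_S:
            soft += n
            total += n
        elif op == _OP_H or op in _QUERY_OPS_NUM:
            total += n
    return soft / total if total else 0.0


def extract_unaligned_set(
    bam_path: str | Path,
    thresholds: Optional[ExtractionThresholds] = None,
    barcode_tag: str = DEFAULT_BARCODE_TAG,
) -> UnalignedSet:
    """Single streaming pass over a SAM/BAM building the set U.

    Mates are matched by read id (works on position-sorted input);
    reads whose mate never appears are dropped with a counter. The
    result is independent of record order.
    """
    thresholds = thresholds or ExtractionThresholds()
    result = UnalignedSet(counts={r: 0 for r in KEEP_REASONS + DROP_REASONS})
    pending: dict = {}
    warned_noqual = False

    mode = "rb" if str(bam_path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(bam_path), mode, check_sq=False) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary or not rec.is_paired:
                continue
            other = pending.pop(rec.query_name, None)
            if other is None:
                pending[rec.query_name] = rec
                continue
            result.n_pairs_seen += 1
            first, second = (other, rec) if other.is_read1 else (rec, other)
            keep, reason = _decide(
                first.is_unmapped,
                first.mapping_quality,
                _clip_stats(first.cigartuples),
                second.is_unmapped,
                second.mapping_quality,
                _clip_stats(second.cigartuples),
                thresholds,
            )
            if not keep:
                result.counts[reason] += 1
                continue
            # Base quality evaluated lazily: only candidates pay for it.
            q1 = first.query_qualities
            q2 = second.query_qualities
            if q1 is None or q2 is None or len(q1) + len(q2) == 0:
                if not warned_noqual:
                    log.warning("pairs without base qualities fail the quality filter")
                    warned_noqual = True
                result.counts["low_base_quality"] += 1
                continue
            a1 = np.frombuffer(q1, dtype=np.uint8)
            a2 = np.frombuffer(q2, dtype=np.uint8)
            if thresholds.quality_mode == "per_mate":
                ok = (
                    a1.mean() > thresholds.min_mean_base_quality
                    and a2.mean() > thresholds.min_mean_base_quality
                )
            else:
                ok = (int(a1.sum()) + int(a2.sum())) / (len(a1) + len(a2)) > (
                    thresholds.min_mean_base_quality
                )
            if not ok:
                result.counts["low_base_quality"] += 1
                continue
            result.counts[reason] += 1
            barcode = (
                first.get_tag(barcode_tag) if first.has_tag(barcode_tag) else None
            )
            if barcode is None and second.has_tag(barcode_tag):
                barcode = second.get_tag(barcode_tag)
            result.pairs.append(
                ExtractedPair(
                    read_id=rec.query_name,
                    barcode=barcode,
                    seq1=first.query_sequence or "",
                    seq2=second.query_sequence or "",
                    qual1=bytes(q1),
                    qual2=bytes(q2),
                    reason=reason,
                )
            )
    result.n_unpaired_dropped = len(pending)
    if pending:
        log.warning("dropped %d reads whose mate was never seen", len(pending))
    # Canonical order regardless of BAM traversal order.
    result.pairs.sort(key=lambda p: p.read_id)
    return result


def write_unaligned_fastq(
    uset: UnalignedSet,
    prefix: str | Path,
    barcode_tag: str = DEFAULT_BARCODE_TAG,
) -> tuple[Path, Path]:
    """Dump U as two FASTQ files (barcodes in comments) plus a JSON summary."""
    prefix = Path(prefix)
    p1 = prefix.with_name(prefix.name + "_1.fastq")
    p2 = prefix.with_name(prefix.name + "_2.fastq")

    def _records(mate: int) -> Iterable[SequenceRecord]:
        for pair in uset.pairs:
            seq = pair.seq1 if mate == 1 else pair.seq2
            qual = pair.qual1 if mate == 1 else pair.qual2
            yield SequenceRecord(
                id=pair.read_id,
                sequence=seq,
                qualities=list(qual),
                barcode=pair.barcode,
            )

    write_fastx(_records(1), p1, barcode_tag=barcode_tag)
    write_fastx(_records(2), p2, barcode_tag=barcode_tag)
    summary = {
        "n_pairs_seen": uset.n_pairs_seen,
        "n_kept": len(uset),
        "n_unpaired_dropped": uset.n_unpaired_dropped,
        "counts": uset.counts,
    }
    with open(prefix.with_name(prefix.name + "_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return p1, p2
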