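"""Placement of anchored contigs on the reference and insertion calling.

Contig-to-reference alignments are first reduced to the subset
maximizing continuously covered contig bases (exact weighted-interval
scheduling, small overlaps tolerated and trimmed). Adjacent alignments
in that chain whose distance is small on the reference but large on
the contig delimit a non-reference insertion; the inserted sequence is
the contig subsequence between them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from ._dna import revcomp
from .io_formats import VariantRecord
from .pairwise_align import LocalAlignment

OVERLAP_TOLERANCE = 10  # bp of contig overlap tolerated between chained alignments


@dataclass
class PlacementParams:
    min_insertion_length: int = 300  # emitted calls must be strictly longer
    min_anchor_sum: int = 300  # left + right anchor must strictly exceed
    max_ref_gap: int = 50  # "small on the reference"
    min_extra_contig_gap: int = 50  # contig gap must exceed ref gap by this
    min_alignment_length: int = 50

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class InsertionCall:
    chrom: str
    breakpoint: int  # 0-based reference base immediately left of the insertion
    inserted_sequence: str  # forward reference strand
    left_anchor_len: int
    right_anchor_len: int
    source_contig_id: str
    ref_gap: int = 0

    @property
    def length(self) -> int:
        return len(self.inserted_sequence)

    @property
    def anchor_sum(self) -> int:
        return self.left_anchor_len + self.right_anchor_len


def best_alignment_subset(
    alignments: Sequence[LocalAlignment],
    overlap_tolerance: int = OVERLAP_TOLERANCE,
) -> list[LocalAlignment]:
    """Exact maximum-coverage chain of alignments of one contig.

    Weighted-interval-scheduling DP over contig coordinates: selects
    the subset of mutually compatible alignments (pairwise contig
    overlap <= tolerance) maximizing the number of contig bases
    covered; ties broken by higher summed score, then fewer alignments.
    Returned sorted by contig start.
    """
    if not alignments:
        return []
    order = sorted(
        range(len(alignments)),
        key=lambda i: (alignments[i].query_end, alignments[i].query_start),
    )
    n = len(order)
    # value[j]: (covered, score, -count) of the best chain ending at order[j]
    value: list[tuple[int, int, int]] = [()] * n  # type: ignore[list-item]
    parent: list[Optional[int]] = [None] * n
    for j in range(n):
        aj = alignments[order[j]]
        best = (aj.query_span, aj.score, -1)
        bp: Optional[int] = None
        for i in range(j):
            ai = alignments[order[i]]
            overlap = ai.query_end - aj.query_start
            if overlap > overlap_tolerance:
                continue
            gain = aj.query_end - max(aj.query_start, ai.query_end)
            cand = (
                value[i][0] + gain,
                value[i][1] + aj.score,
                value[i][2] - 1,
            )
            if cand > best:
                best = cand
                bp = i
        value[j] = best
        parent[j] = bp
    end = max(range(n), key=lambda j: value[j])
    chain_idx = []
    cur: Optional[int] = end
    while cur is not None:
        chain_idx.append(order[cur])
        cur = parent[cur]
    chain = [alignments[i] for i in reversed(chain_idx)]
    return _trim_overlaps(chain, overlap_tolerance)


def _trim_overlaps(
    chain: list[LocalAlignment], tolerance: int
) -> list[LocalAlignment]:
    """Trim tolerated contig overlaps off the right member of each pair."""
    import copy

    out: list[LocalAlignment] = []
    for aln in chain:
        if out:
            overlap = out[-1].query_end - aln.query_start
            if 0 < overlap <= tolerance:
                aln = copy.copy(aln)
                aln.query_start += overlap
                if aln.strand == "+":
                    aln.target_start += overlap
                else:
                    aln.target_end -= overlap
                aln.cigar = [("M", aln.query_span)]
        out.append(aln)
    return out


def chain_strand(chain: Sequence[LocalAlignment]) -> str:
    """Majority strand of a chain, weighted by aligned contig bases."""
    fwd = sum(a.query_span for a in chain if a.strand == "+")
    rev = sum(a.query_span for a in chain if a.strand == "-")
    return "+" if fwd >= rev else "-"


def call_insertions(
    chain: Sequence[LocalAlignment],
    contig_id: str,
    contig_seq: str,
    params: Optional[PlacementParams] = None,
) -> list[InsertionCall]:
    """Scan adjacent chain pairs for the insertion signature.

    A junction qualifies when both alignments share chromosome and
    strand, the reference gap is at most ``max_ref_gap`` and the contig
    gap exceeds the reference gap by at least ``min_extra_contig_gap``.
    Junctions across chromosomes or strands yield no call. The caller
    is expected to have canonicalized a reverse-mapping contig (see
    :func:`chain_strand`); reverse-strand junctions are still handled,
    with the inserted sequence reported on the forward strand.
    """
    params = params or PlacementParams()
    calls: list[InsertionCall] = []
    for left, right in zip(chain, chain[1:]):
        if left.target_id != right.target_id or left.strand != right.strand:
            continue
        contig_gap = right.query_start - left.query_end
        if left.strand == "+":
            ref_gap = right.target_start - left.target_end
        else:
            ref_gap = left.target_start - right.target_end
        if ref_gap > params.max_ref_gap or ref_gap < -OVERLAP_TOLERANCE:
            continue
        if contig_gap - max(ref_gap, 0) < params.min_extra_contig_gap:
            continue
        seq = contig_seq[left.query_end : right.query_start]
        if left.strand == "+":
            breakpoint = left.target_end - 1
            left_len, right_len = left.target_span, right.target_span
        else:
            seq = revcomp(seq)
            breakpoint = right.target_end - 1
            left_len, right_len = right.target_span, left.target_span
        if min(left_len, right_len) < params.min_alignment_length:
            continue
        calls.append(
            InsertionCall(
                chrom=left.target_id,
                breakpoint=breakpoint,
                inserted_sequence=seq,
                left_anchor_len=left_len,
                right_anchor_len=right_len,
                source_contig_id=contig_id,
                ref_gap=max(ref_gap, 0),
            )
        )
    return calls


def dedupe_calls(
    calls: Sequence[InsertionCall],
    max_distance: int = 100,
    max_length_diff: float = 0.05,
) -> list[InsertionCall]:
    """Collapse near-identical calls from different source contigs.

    Several orphan contigs can describe the same event; among calls
    within ``max_distance`` bp whose lengths agree within
    ``max_length_diff``, the one with the largest anchor sum survives.
    """
    ordered = sorted(
        calls, key=lambda c: (c.chrom, c.breakpoint, -c.anchor_sum, c.source_contig_id)
    )
    kept: list[InsertionCall] = []
    for call in ordered:
        dup = False
        for other in kept:
            if other.chrom != call.chrom:
                continue
            if abs(other.breakpoint - call.breakpoint) > max_distance:
                continue
            longer = max(other.length, call.length)
            if abs(other.length - call.length) / longer <= max_length_diff:
                dup = True
                if call.anchor_sum > other.anchor_sum:
                    kept[kept.index(other)] = call
                break
        if not dup:
            kept.append(call)
    kept.sort(key=lambda c: (c.chrom, c.breakpoint))
    return kept


def variant_from_call(call: InsertionCall, reference: Mapping[str, str]) -> VariantRecord:
    """0-based breakpoint -> 1-based VCF record with the full ALT sequence."""
    ref_base = str(reference[call.chrom][call.breakpoint]).upper()
    info = {
        "SVLEN": call.length,
        "LEFT_ANCHOR": call.left_anchor_len,
        "RIGHT_ANCHOR": call.right_anchor_len,
        "CONTIG_ID": call.source_contig_id,
    }
    if call.ref_gap:
        info["REFGAP"] = call.ref_gap
    return VariantRecord(
        chrom=call.chrom,
        pos=call.breakpoint + 1,
        ref_allele=ref_base,
        alt_allele=ref_base + call.inserted_sequence,
        info=info,
    )


def filter_and_emit(
    calls: Sequence[InsertionCall],
    reference: Mapping[str, str],
    params: Optional[PlacementParams] = None,
) -> tuple[list[VariantRecord], list[InsertionCall]]:
    """Split calls into VCF-worthy and secondary-file records.

    The VCF receives calls strictly longer than ``min_insertion_length``
    whose anchor sum strictly exceeds ``min_anchor_sum``; everything
    else (e.g. smaller insertions) goes to the secondary list. Both
    outputs are sorted.
    """
    params = params or PlacementParams()
    primary: list[VariantRecord] = []
    secondary: list[InsertionCall] = []
    for call in sorted(calls, key=lambda c: (c.chrom, c.breakpoint)):
        if call.length > params.min_insertion_length and call.anchor_sum > params.min_anchor_sum:
            primary.append(variant_from_call(call, reference))
        else:
            secondary.append(call)
    return primary, secondary


def write_secondary_tsv(calls: Sequence[InsertionCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tlength\tleft_anchor\tright_anchor\tcontig\tsequence\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.breakpoint + 1}\t{c.length}\t{c.left_anchor_len}"
                f"\t{c.right_anchor_len}\t{c.source_contig_id}\t{c.inserted_sequence}\n"
            )
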