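"""Readers/writers for the standard formats the pipeline touches.

Conventions (fixed across the package):

* internal coordinates are 0-based half-open everywhere;
* VCF is 1-based at the serialization boundary only;
* CLI region strings follow the samtools 1-based inclusive convention;
* secondary and supplementary alignment records are ignored.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Optional, Sequence

import pysam
from Bio import SeqIO

log = logging.getLogger(__name__)

DEFAULT_BARCODE_TAG = "BX"

# CIGAR operation characters indexed by the pysam/BAM numeric opcode.
_CIGAR_OPS = "MIDNSHP=X"
_QUERY_OPS = set("MIS=X")  # operations that consume query sequence
_CLIP_OPS = set("SH")


@dataclass
class SequenceRecord:
    """One FASTA/FASTQ record, optionally carrying a barcode."""

    id: str
    sequence: str
    qualities: Optional[list[int]] = None
    barcode: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"record {self.id!r}: quality/sequence length mismatch")


@dataclass
class AlignedRead:
    """One mate of a barcoded read pair with its alignment state."""

    read_id: str
    mate_index: int  # 1 or 2
    barcode: Optional[str]
    is_mapped: bool
    is_reverse: bool
    mate_is_mapped: bool
    ref_name: Optional[str]
    ref_start: int  # 0-based; -1 when unmapped
    cigar: list[tuple[str, int]]
    mapq: int
    sequence: str
    qualities: list[int]

    def query_consumed_length(self) -> int:
        """Full query length implied by the CIGAR, hard clips included."""
        return sum(n for op, n in self.cigar if op in _QUERY_OPS or op == "H")


@dataclass
class VariantRecord:
    """A placed insertion ready for VCF serialization (pos is 1-based)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("VCF positions are 1-based")
        if len(self.ref_allele) != 1:
            raise ValueError("ref allele must be a single base")
        if len(self.alt_allele) < 2 or self.alt_allele[0] != self.ref_allele:
            raise ValueError("alt allele must be ref base + inserted sequence")

    @property
    def svlen(self) -> int:
        return len(self.alt_allele) - 1


def parse_region(region: str) -> tuple[str, Optional[int], Optional[int]]:
    """Parse a samtools-style 1-based inclusive region into 0-based half-open.

    ``"chr1:100-200"`` -> ``("chr1", 99, 200)``; ``"chr1"`` -> ``("chr1", None, None)``.
    """
    m = re.fullmatch(r"([^:]+)(?::([\d,]+)-([\d,]+))?", region)
    if not m:
        raise ValueError(f"cannot parse region {region!r}")
    chrom, s, e = m.groups()
    if s is None:
        return chrom, None, None
    start = int(s.replace(",", "")) - 1
    end = int(e.replace(",", ""))
    if start < 0 or end <= start:
        raise ValueError(f"invalid region {region!r}")
    return chrom, start, end


def _aligned_read_from_pysam(rec: pysam.AlignedSegment, barcode_tag: str) -> AlignedRead:
    barcode = rec.get_tag(barcode_tag) if rec.has_tag(barcode_tag) else None
    cigar = (
        [(_CIGAR_OPS[op], ln) for op, ln in rec.cigartuples]
        if rec.cigartuples
        else []
    )
    quals = list(rec.query_qualities) if rec.query_qualities is not None else []
    return AlignedRead(
        read_id=rec.query_name,
        mate_index=2 if rec.is_read2 else 1,
        barcode=barcode,
        is_mapped=not rec.is_unmapped,
        is_reverse=rec.is_reverse,
        mate_is_mapped=not rec.mate_is_unmapped if rec.is_paired else True,
        ref_name=rec.reference_name if not rec.is_unmapped else None,
        ref_start=rec.reference_start if not rec.is_unmapped else -1,
        cigar=cigar,
        mapq=rec.mapping_quality,
        sequence=rec.query_sequence or "",
        qualities=quals,
    )


def read_alignments(
    path: str | Path,
    region: Optional[tuple[str, Optional[int], Optional[int]]] = None,
    barcode_tag: str = DEFAULT_BARCODE_TAG,
) -> Iterator[AlignedRead]:
    """Yield every primary record of a SAM/BAM file as :class:`AlignedRead`.

    ``region`` is 0-based half-open (use :func:`parse_region` for CLI
    strings) and requires an index. Secondary/supplementary records are
    skipped; malformed records are skipped with a logged warning.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    skipped = 0
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as bam:
        if region is not None:
            chrom, start, end = region
            it: Iterable[pysam.AlignedSegment] = bam.fetch(chrom, start, end)
        else:
            it = bam.fetch(until_eof=True)
        for rec in it:
            if rec.is_secondary or rec.is_supplementary:
                continue
            try:
                yield _aligned_read_from_pysam(rec, barcode_tag)
            except (ValueError, KeyError) as exc:  # malformed record
                skipped += 1
                log.warning("skipping malformed record %s: %s", rec.query_name, exc)
    if skipped:
        log.warning("skipped %d malformed records in %s", skipped, path)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_INFO_ORDER = ("SVLEN", "LEFT_ANCHOR", "RIGHT_ANCHOR", "CONTIG_ID", "REFGAP")

_VCF_HEADER_LINES = [
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Inserted sequence length">',
    '##INFO=<ID=LEFT_ANCHOR,Number=1,Type=Integer,Description="Left anchor alignment length">',
    '##INFO=<ID=RIGHT_ANCHOR,Number=1,Type=Integer,Description="Right anchor alignment length">',
    '##INFO=<ID=CONTIG_ID,Number=1,Type=String,Description="Source assembled contig">',
    '##INFO=<ID=REFGAP,Number=1,Type=Integer,Description="Unaligned reference bases at the junction">',
]


def write_vcf(
    calls: Sequence[VariantRecord],
    reference: Mapping[str, str],
    path: str | Path,
) -> None:
    """Write insertion calls as VCF 4.2, sorted by (chrom, pos).

    ``reference`` maps chromosome name to sequence (a ``pyfaidx.Fasta``
    works). Each call's ref allele is checked against the reference; a
    mismatch is fatal because it signals a coordinate bug upstream.
    """
    order = {name: i for i, name in enumerate(reference.keys())}
    for call in calls:
        if call.chrom not in order:
            raise ValueError(f"call chromosome {call.chrom!r} absent from reference")
        ref_base = str(reference[call.chrom][call.pos - 1 : call.pos]).upper()
        if ref_base != call.ref_allele.upper():
            raise ValueError(
                f"{call.chrom}:{call.pos}: ref allele {call.ref_allele!r} does not "
                f"match reference base {ref_base!r}"
            )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in reference.keys():
            fh.write(f"##contig=<ID={name},length={len(reference[name])}>\n")
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for call in sorted(calls, key=lambda c: (order[c.chrom], c.pos)):
            known = [
                f"{k}={call.info[k]}" for k in _VCF_INFO_ORDER if k in call.info
            ]
            extra = [
                f"{k}={v}" for k, v in call.info.items() if k not in _VCF_INFO_ORDER
            ]
            info = ";".join(known + extra) or "."
            fh.write(
                f"{call.chrom}\t{call.pos}\t.\t{call.ref_allele}\t{call.alt_allele}"
                f"\t.\tPASS\t{info}\n"
            )


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read the body of a VCF produced by :func:`write_vcf`."""
    out: list[VariantRecord] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _id, ref, alt, _qual, _filt, info = line.rstrip("\n").split("\t")[:8]
            info_map: dict = {}
            if info != ".":
                for item in info.split(";"):
                    k, _, v = item.partition("=")
                    try:
                        info_map[k] = int(v)
                    except ValueError:
                        info_map[k] = v
            out.append(VariantRecord(chrom, int(pos), ref, alt, info_map))
    return out


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def _open_text(path: str | Path, mode: str) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _is_fastq(path: str | Path) -> bool:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    return name.endswith((".fastq", ".fq"))


def read_fastx(
    path: str | Path, barcode_tag: str = DEFAULT_BARCODE_TAG
) -> Iterator[SequenceRecord]:
    """Stream records from FASTA/FASTQ (optionally gzipped).

    For FASTQ, a ``TAG:Z:value`` token in the read comment (default tag
    ``BX``) is parsed into ``SequenceRecord.barcode``.
    """
    fmt = "fastq" if _is_fastq(path) else "fasta"
    prefix = f"{barcode_tag}:Z:"
    with _open_text(path, "r") as fh:
        for rec in SeqIO.parse(fh, fmt):
            barcode = None
            for token in rec.description.split()[1:]:
                if token.startswith(prefix):
                    barcode = token[len(prefix):]
                    break
            quals = rec.letter_annotations.get("phred_quality")
            yield SequenceRecord(
                id=rec.id,
                sequence=str(rec.seq),
                qualities=list(quals) if quals is not None else None,
                barcode=barcode,
            )


def write_fastx(
    records: Iterable[SequenceRecord],
    path: str | Path,
    barcode_tag: str = DEFAULT_BARCODE_TAG,
) -> None:
    """Write records as FASTA or FASTQ depending on the file extension."""
    fastq = _is_fastq(path)
    with _open_text(path, "w") as fh:
        for rec in records:
            comment = f" {barcode_tag}:Z:{rec.barcode}" if rec.barcode else ""
            if fastq:
                if rec.qualities is None:
                    raise ValueError(f"record {rec.id!r} lacks qualities for FASTQ")
                qual = "".join(chr(q + 33) for q in rec.qualities)
                fh.write(f"@{rec.id}{comment}\n{rec.sequence}\n+\n{qual}\n")
            else:
                fh.write(f">{rec.id}{comment}\n{rec.sequence}\n")


def read_fasta_dict(path: str | Path) -> dict[str, str]:
    """Load a (small) FASTA file fully into a name -> sequence dict."""
    return {rec.id: rec.sequence for rec in read_fastx(path)}
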