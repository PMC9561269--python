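"""Shared fixtures: tiny in-memory BAM construction and random sequences."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pysam
import pytest

from nrscall._dna import random_dna


@dataclass
class ReadSpec:
    """Declarative description of one BAM record for test construction."""

    qname: str
    seq: str
    flag_read1: bool = True
    unmapped: bool = False
    reverse: bool = False
    mate_unmapped: bool = False
    ref_start: int = 0
    mapq: int = 60
    cigar: Optional[list[tuple[int, int]]] = None  # pysam numeric ops
    barcode: Optional[str] = None
    qualities: Optional[list[int]] = None
    tid: int = 0


def build_bam(path: Path, specs: list[ReadSpec], ref_lengths: dict[str, int], sort: bool = True) -> Path:
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": n, "LN": l} for n, l in ref_lengths.items()],
        }
    )
    tmp = path.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(tmp), "wb", header=header) as bam:
        for s in specs:
            rec = pysam.AlignedSegment(header)
            rec.query_name = s.qname
            rec.query_sequence = s.seq
            flag = 0x1 | (0x40 if s.flag_read1 else 0x80)
            if s.unmapped:
                flag |= 0x4
            if s.reverse:
                flag |= 0x10
            if s.mate_unmapped:
                flag |= 0x8
            rec.flag = flag
            if not s.unmapped:
                rec.reference_id = s.tid
                rec.reference_start = s.ref_start
                rec.mapping_quality = s.mapq
                rec.cigartuples = s.cigar or [(0, len(s.seq))]
            else:
                rec.reference_id = s.tid
                rec.reference_start = s.ref_start
            quals = s.qualities if s.qualities is not None else [30] * len(s.seq)
            rec.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in quals)
            )
            if s.barcode:
                rec.set_tag("BX", s.barcode, "Z")
            bam.write(rec)
    if sort:
        pysam.sort("-o", str(path), str(tmp))
        tmp.unlink()
        pysam.index(str(path))
    else:
        tmp.rename(path)
    return path


@pytest.fixture
def bam_factory(tmp_path):
    counter = {"n": 0}

    def _make(specs: list[ReadSpec], ref_lengths=None, sort=True) -> Path:
        counter["n"] += 1
        ref_lengths = ref_lengths or {"chr1": 100_000}
        return build_bam(tmp_path / f"test{counter['n']}.bam", specs, ref_lengths, sort)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Apply exactly n distinct substitutions."""
    out = list(seq)
    for p in rng.choice(len(seq), size=n_subs, replace=False):
        out[p] = "ACGT"[("ACGT".index(out[p]) + 1 + int(rng.integers(3))) % 4]
    return "".join(out)


__all__ = ["ReadSpec", "build_bam", "mutate", "random_dna"]
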