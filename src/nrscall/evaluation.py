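"""Benchmarking of insertion callsets against truth or each other.

Two insertions are the same event when their breakpoints are within
100 bp and their lengths agree within 5% (of the longer one); sequence
content is optionally validated by global alignment at 80% identity.
Results are summarized with precision/recall and the standard length
bins (50-299, 300-499, 500-999, 1000-1999, 2000-4999, >=5000).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam
from scipy.optimize import linear_sum_assignment

from ._dna import revcomp
from .pairwise_align import AlignParams, global_identity

LENGTH_BINS: tuple[tuple[int, float], ...] = (
    (50, 300),
    (300, 500),
    (500, 1000),
    (1000, 2000),
    (2000, 5000),
    (5000, float("inf")),
)


def bin_label(lo: int, hi: float) -> str:
    return f"{lo}-{int(hi) - 1}" if hi != float("inf") else f">={lo}"


def length_bin(length: int) -> Optional[str]:
    for lo, hi in LENGTH_BINS:
        if lo <= length < hi:
            return bin_label(lo, hi)
    return None  # < 50 bp: outside the benchmark's domain


@dataclass
class MatchCriteria:
    max_breakpoint_distance: int = 100
    max_length_diff: float = 0.05
    min_content_identity: float = 0.80


@dataclass
class BenchCall:
    """Minimal call representation for matching (0-based breakpoint)."""

    chrom: str
    breakpoint: int
    length: int
    sequence: Optional[str] = None
    sample: Optional[str] = None


@dataclass
class BenchmarkResult:
    tp: int
    fp: int
    fn: int
    per_bin: dict = field(default_factory=dict)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "per_bin": self.per_bin,
        }


def eligible(a: BenchCall, b: BenchCall, criteria: MatchCriteria) -> bool:
    if a.chrom != b.chrom:
        return False
    if abs(a.breakpoint - b.breakpoint) > criteria.max_breakpoint_distance:
        return False
    longer = max(a.length, b.length)
    if longer == 0:
        return False
    return abs(a.length - b.length) / longer <= criteria.max_length_diff


def match_calls(
    calls: Sequence[BenchCall],
    truth: Sequence[BenchCall],
    criteria: Optional[MatchCriteria] = None,
) -> list[tuple[int, int]]:
    """Optimal one-to-one matching of calls to truth records.

    Each call and each truth record is used at most once; among all
    matchings the one with maximum cardinality and, within that, the
    smallest total breakpoint distance is chosen (Hungarian algorithm
    with a prohibitive cost on ineligible pairs). Returns (call index,
    truth index) pairs sorted by call index.
    """
    criteria = criteria or MatchCriteria()
    n, m = len(calls), len(truth)
    if n == 0 or m == 0:
        return []
    big = np.int64(10) ** 12
    cost = np.full((n, m), big, dtype=np.int64)
    # windowed candidate generation: only nearby truths can be eligible
    order = sorted(range(m), key=lambda ti: (truth[ti].chrom, truth[ti].breakpoint))
    t_chroms = [truth[ti].chrom for ti in order]
    t_pos = [truth[ti].breakpoint for ti in order]
    t_keys = list(zip(t_chroms, t_pos))
    import bisect

    any_eligible = False
    for ci, c in enumerate(calls):
        lo = bisect.bisect_left(
            t_keys, (c.chrom, c.breakpoint - criteria.max_breakpoint_distance)
        )
        for k in range(lo, m):
            if t_chroms[k] != c.chrom or t_pos[k] > c.breakpoint + criteria.max_breakpoint_distance:
                break
            ti = order[k]
            if eligible(c, truth[ti], criteria):
                cost[ci, ti] = abs(c.breakpoint - truth[ti].breakpoint)
                any_eligible = True
    if not any_eligible:
        return []
    rows, cols = linear_sum_assignment(cost)
    matching = [
        (int(ci), int(ti)) for ci, ti in zip(rows, cols) if cost[ci, ti] < big
    ]
    matching.sort()
    return matching


def content_match(
    call: BenchCall,
    truth: BenchCall,
    criteria: Optional[MatchCriteria] = None,
    align_params: Optional[AlignParams] = None,
) -> bool:
    """Global-alignment identity check, strand-canonicalized."""
    criteria = criteria or MatchCriteria()
    if not call.sequence or not truth.sequence:
        raise ValueError("content_match requires sequences on both records")
    fwd = global_identity(call.sequence, truth.sequence, align_params)
    if fwd >= criteria.min_content_identity:
        return True
    rev = global_identity(call.sequence, revcomp(truth.sequence), align_params)
    return rev >= criteria.min_content_identity


def summarize(
    matching: Sequence[tuple[int, int]],
    calls: Sequence[BenchCall],
    truth: Sequence[BenchCall],
) -> BenchmarkResult:
    """Precision/recall with per-bin breakdown.

    TP and FN are binned by truth length, FP by call length; records
    shorter than 50 bp fall outside all bins but still count in the
    totals.
    """
    matched_calls = {ci for ci, _ in matching}
    matched_truth = {ti for _, ti in matching}
    per_bin = {
        bin_label(lo, hi): {"tp": 0, "fp": 0, "fn": 0, "truth": 0}
        for lo, hi in LENGTH_BINS
    }
    for _, ti in matching:
        b = length_bin(truth[ti].length)
        if b:
            per_bin[b]["tp"] += 1
    for ti, t in enumerate(truth):
        b = length_bin(t.length)
        if b:
            per_bin[b]["truth"] += 1
            if ti not in matched_truth:
                per_bin[b]["fn"] += 1
    for ci, c in enumerate(calls):
        if ci not in matched_calls:
            b = length_bin(c.length)
            if b:
                per_bin[b]["fp"] += 1
    return BenchmarkResult(
        tp=len(matching),
        fp=len(calls) - len(matching),
        fn=len(truth) - len(matching),
        per_bin=per_bin,
    )


def benchmark(
    calls: Sequence[BenchCall],
    truth: Sequence[BenchCall],
    criteria: Optional[MatchCriteria] = None,
) -> tuple[list[tuple[int, int]], BenchmarkResult]:
    matching = match_calls(calls, truth, criteria)
    return matching, summarize(matching, calls, truth)


# ---------------------------------------------------------------------------
# Conversions
# ---------------------------------------------------------------------------


def calls_from_vcf(path: str | Path, sample: Optional[str] = None) -> list[BenchCall]:
    from .io_formats import read_vcf

    return [
        BenchCall(
            chrom=rec.chrom,
            breakpoint=rec.pos - 1,
            length=len(rec.alt_allele) - 1,
            sequence=rec.alt_allele[1:],
            sample=sample,
        )
        for rec in read_vcf(path)
    ]


def calls_from_secondary_tsv(path: str | Path, sample: Optional[str] = None) -> list[BenchCall]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            out.append(
                BenchCall(
                    chrom=row["chrom"],
                    breakpoint=int(row["pos"]) - 1,
                    length=int(row["length"]),
                    sequence=row.get("sequence") or None,
                    sample=sample,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Cohort operations
# ---------------------------------------------------------------------------


def cluster_uis(
    calls: Iterable[BenchCall], bin_size: int = 10_000
) -> dict[tuple[str, int], list[str]]:
    """Unique insertion sites: occupied (chrom, breakpoint // bin_size) bins.

    Returns bin -> sorted list of distinct samples carrying a call there.
    """
    uis: dict[tuple[str, int], set[str]] = {}
    for call in calls:
        key = (call.chrom, call.breakpoint // bin_size)
        uis.setdefault(key, set()).add(call.sample or "sample")
    return {key: sorted(samples) for key, samples in sorted(uis.items())}


def uis_counts_per_sample(uis: dict[tuple[str, int], list[str]]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for samples in uis.values():
        for s in samples:
            counts[s] = counts.get(s, 0) + 1
    return dict(sorted(counts.items()))


def ancestry_unique_uis(
    uis: dict[tuple[str, int], list[str]],
    sample_groups: dict[str, str],
    min_group_fraction: float = 0.80,
) -> dict[tuple[str, int], str]:
    """UIS present in >= min_group_fraction of exactly one ancestry group."""
    group_sizes: dict[str, int] = {}
    for group in sample_groups.values():
        group_sizes[group] = group_sizes.get(group, 0) + 1
    out: dict[tuple[str, int], str] = {}
    for key, samples in uis.items():
        hits: dict[str, int] = {}
        for s in samples:
            group = sample_groups.get(s)
            if group:
                hits[group] = hits.get(group, 0) + 1
        frequent = [
            g for g, n in hits.items() if n / group_sizes[g] >= min_group_fraction
        ]
        if len(frequent) == 1:
            out[key] = frequent[0]
    return out


def barcode_concordance(
    call: BenchCall,
    barcodes: set[str],
    bam_path: str | Path,
    window: int = 10_000,
    barcode_tag: str = "BX",
) -> float:
    """Fraction of a call's recruited barcodes seen near its breakpoint.

    Scans the indexed BAM in a +/- window/2 interval around the
    breakpoint (clipped to the chromosome) and intersects the observed
    barcodes with the call's B(c).
    """
    if not barcodes:
        raise ValueError("call carries no barcode list")
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        chrom_len = bam.get_reference_length(call.chrom)
        start = max(0, call.breakpoint - window // 2)
        end = min(chrom_len, call.breakpoint + window // 2)
        seen: set[str] = set()
        for rec in bam.fetch(call.chrom, start, end):
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.has_tag(barcode_tag):
                seen.add(rec.get_tag(barcode_tag))
    return len(barcodes & seen) / len(barcodes)


def write_benchmark_json(result: BenchmarkResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
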