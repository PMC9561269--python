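"""Linked-read simulator with implanted insertions and analytic truth BAMs.

The donor genome is the reference with random insertion sequences
implanted at spaced uniform positions. Long molecules are sheared from
the donor (lengths exponential above a 1 kb floor, so the configured
mean is the distribution mean), tagged with barcodes, and barcoded read
pairs are sampled from molecules at the configured depth.

Truth-BAM mode places every read analytically from the known
donor-to-reference coordinate map: reads overlapping an insertion are
soft-clipped exactly at the boundary (the longer reference-consistent
side is kept) and reads living entirely inside inserted sequence are
unmapped -- i.e. what a faithful aligner would do, with no aligner in
the loop. Substitution errors are applied after placement so
non-insertion reads align at their true coordinates regardless.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pysam

from ._dna import decode, revcomp
from .io_formats import VariantRecord, write_vcf

CHROM = "chr1"
_MIN_MAPPED = 20  # bases an aligner needs to anchor a clipped read

_OP_M, _OP_S = 0, 4


@dataclass
class SimulationConfig:
    reference_length: int = 5_000_000
    n_insertions: int = 20
    insertion_length_range: tuple[int, int] = (50, 6000)
    coverage: float = 65.0
    read_length: int = 150
    insert_size_mean: float = 400.0
    insert_size_sd: float = 50.0
    molecule_length_mean: float = 50_000.0
    molecule_length_min: float = 1_000.0
    molecules_per_barcode: int = 10
    n_barcodes: Optional[int] = None  # derived from molecule_coverage if None
    molecule_coverage: float = 0.3  # read depth within one molecule
    substitution_error_rate: float = 0.001
    base_quality: int = 37
    min_insertion_spacing: Optional[int] = None  # None -> 2 * molecule_length_mean
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.insertion_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid insertion length range")
        if self.molecule_length_mean <= self.molecule_length_min:
            raise ValueError("molecule_length_mean must exceed the 1 kb floor")
        if self.min_insertion_spacing is None:
            self.min_insertion_spacing = int(2 * self.molecule_length_mean)

    @property
    def n_pairs(self) -> int:
        return int(round(self.coverage * self.reference_length / (2 * self.read_length)))


@dataclass
class TruthRecord:
    chrom: str
    breakpoint: int  # 0-based reference base immediately left of the insertion
    sequence: str


@dataclass
class TruthSet:
    records: list[TruthRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class MoleculeStat:
    barcode: str
    chrom: str
    start: int
    end: int
    molecule_length: int
    molecule_coverage: float


@dataclass
class SimulationResult:
    reference_fasta: Path
    donor_fasta: Path
    truth_vcf: Path
    truth_bam: Path
    fastq1: Optional[Path]
    fastq2: Optional[Path]
    truth: TruthSet
    n_pairs: int
    n_barcodes: int


def _spaced_positions(
    rng: np.random.Generator, n: int, genome_length: int, spacing: int
) -> np.ndarray:
    """n sorted positions in [spacing, G - spacing] pairwise >= spacing apart."""
    slack = genome_length - 2 * spacing - (n - 1) * spacing
    if n > 0 and slack <= 0:
        raise ValueError(
            f"genome of {genome_length} bp cannot hold {n} insertions "
            f"spaced >= {spacing} bp apart"
        )
    u = np.sort(rng.random(n)) * slack
    return (spacing + u + np.arange(n) * spacing).astype(np.int64)


def _write_fasta(path: Path, name: str, enc: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        seq = decode(enc)
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")


def simulate(
    config: SimulationConfig, outdir: str | Path, emit_fastq: bool = False
) -> SimulationResult:
    """Run the full simulation; byte-reproducible from ``config.seed``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    G = config.reference_length
    rl = config.read_length

    ref_enc = rng.integers(0, 4, size=G, dtype=np.uint8)

    lo, hi = config.insertion_length_range
    ins_lens = rng.integers(lo, hi + 1, size=config.n_insertions).astype(np.int64)
    ins_pos = _spaced_positions(
        rng, config.n_insertions, G, int(config.min_insertion_spacing)
    )  # insertion goes immediately before reference base ins_pos[i]
    ins_seqs = [rng.integers(0, 4, size=int(l), dtype=np.uint8) for l in ins_lens]

    # Donor assembly + donor coordinates of the inserted segments.
    parts = []
    ins_starts_donor = np.zeros(config.n_insertions, dtype=np.int64)
    cum_ins = np.zeros(config.n_insertions + 1, dtype=np.int64)
    prev = 0
    for i in range(config.n_insertions):
        parts.append(ref_enc[prev : ins_pos[i]])
        ins_starts_donor[i] = ins_pos[i] + cum_ins[i]
        parts.append(ins_seqs[i])
        cum_ins[i + 1] = cum_ins[i] + ins_lens[i]
        prev = int(ins_pos[i])
    parts.append(ref_enc[prev:])
    donor_enc = np.concatenate(parts) if parts else ref_enc
    ins_ends_donor = ins_starts_donor + ins_lens
    Gd = len(donor_enc)

    truth = TruthSet(
        [
            TruthRecord(CHROM, int(ins_pos[i]) - 1, decode(ins_seqs[i]))
            for i in range(config.n_insertions)
        ]
    )

    ref_fa = outdir / "reference.fasta"
    donor_fa = outdir / "donor.fasta"
    _write_fasta(ref_fa, CHROM, ref_enc)
    _write_fasta(donor_fa, CHROM, donor_enc)

    truth_vcf = outdir / "truth.vcf"
    ref_seq_str = decode(ref_enc)
    calls = [
        VariantRecord(
            CHROM,
            rec.breakpoint + 1,
            ref_seq_str[rec.breakpoint],
            ref_seq_str[rec.breakpoint] + rec.sequence,
            {"SVLEN": len(rec.sequence)},
        )
        for rec in truth.records
    ]
    write_vcf(calls, {CHROM: ref_seq_str}, truth_vcf)

    # --- molecules ---------------------------------------------------------
    if config.n_barcodes is None:
        total_mol_bases = config.coverage * G / config.molecule_coverage
        n_barcodes = max(
            1,
            int(
                round(
                    total_mol_bases
                    / (config.molecules_per_barcode * config.molecule_length_mean)
                )
            ),
        )
    else:
        n_barcodes = config.n_barcodes
    n_molecules = n_barcodes * config.molecules_per_barcode
    scale = config.molecule_length_mean - config.molecule_length_min
    mol_len = (
        config.molecule_length_min + rng.exponential(scale, size=n_molecules)
    ).astype(np.int64)
    np.minimum(mol_len, Gd, out=mol_len)
    mol_start = (rng.random(n_molecules) * (Gd - mol_len + 1)).astype(np.int64)
    mol_barcode = np.arange(n_molecules) // config.molecules_per_barcode

    # --- read pairs --------------------------------------------------------
    n_pairs = config.n_pairs
    p = mol_len / mol_len.sum()
    pairs_per_mol = rng.multinomial(n_pairs, p)
    pair_mol = np.repeat(np.arange(n_molecules), pairs_per_mol)
    pl = mol_len[pair_mol]
    frag = np.clip(
        np.rint(rng.normal(config.insert_size_mean, config.insert_size_sd, size=len(pair_mol))),
        2 * rl,
        pl,
    ).astype(np.int64)
    off = (rng.random(len(pair_mol)) * (pl - frag + 1)).astype(np.int64)
    frag_start = mol_start[pair_mol] + off
    frag_end = frag_start + frag
    fwd_is_read1 = rng.random(len(pair_mol)) < 0.5

    # mate A: forward at fragment start; mate B: reverse at fragment end
    a_start, a_end = frag_start, frag_start + rl
    b_start, b_end = frag_end - rl, frag_end

    def _place(starts: np.ndarray, ends: np.ndarray):
        """Vectorized truth placement of donor intervals on the reference.

        Returns (ref_start, n_prefix_mapped, n_suffix_mapped, mapped) where
        exactly one of prefix/suffix is nonzero for clipped reads.
        """
        j_first = np.searchsorted(ins_ends_donor, starts, side="right")
        j_last = np.searchsorted(ins_starts_donor, ends, side="left") - 1
        if config.n_insertions == 0:
            no_overlap = np.ones(len(starts), dtype=bool)
        else:
            next_start = np.where(
                j_first < config.n_insertions,
                ins_starts_donor[np.minimum(j_first, config.n_insertions - 1)],
                Gd + 1,
            )
            no_overlap = (j_first >= config.n_insertions) | (next_start >= ends)
        prefix = np.zeros(len(starts), dtype=np.int64)
        suffix = np.zeros(len(starts), dtype=np.int64)
        ref_start = np.zeros(len(starts), dtype=np.int64)
        mapped = np.ones(len(starts), dtype=bool)
        clean = np.nonzero(no_overlap)[0]
        ref_start[clean] = starts[clean] - cum_ins[j_first[clean]]
        prefix[clean] = ends[clean] - starts[clean]
        for i in np.nonzero(~no_overlap)[0]:
            jf, jl = j_first[i], j_last[i]
            pre = max(0, int(ins_starts_donor[jf]) - int(starts[i]))
            suf = max(0, int(ends[i]) - int(ins_ends_donor[jl]))
            if max(pre, suf) < _MIN_MAPPED:
                mapped[i] = False
                continue
            if pre >= suf:
                prefix[i] = pre
                ref_start[i] = starts[i] - cum_ins[jf]
            else:
                suffix[i] = suf
                ref_start[i] = ins_ends_donor[jl] - cum_ins[jl + 1]
        return ref_start, prefix, suffix, mapped

    a_ref, a_pre, a_suf, a_mapped = _place(a_start, a_end)
    b_ref, b_pre, b_suf, b_mapped = _place(b_start, b_end)

    # --- sequences and errors ---------------------------------------------
    n_reads = 2 * len(pair_mol)
    err_counts = rng.binomial(rl, config.substitution_error_rate, size=n_reads)

    qual = pysam.qualitystring_to_array(chr(config.base_quality + 33) * rl)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": CHROM, "LN": G}],
        }
    )

    unsorted_bam = outdir / "truth.unsorted.bam"
    truth_bam = outdir / "truth.bam"
    fq1 = outdir / "reads_1.fastq" if emit_fastq else None
    fq2 = outdir / "reads_2.fastq" if emit_fastq else None
    fq1_fh = open(fq1, "w") if emit_fastq else None
    fq2_fh = open(fq2, "w") if emit_fastq else None
    qual_str = chr(config.base_quality + 33) * rl

    def _mutate(seq_enc: np.ndarray, k: int) -> np.ndarray:
        if k == 0:
            return seq_enc
        out = seq_enc.copy()
        pos = rng.integers(0, rl, size=k)
        out[pos] = (out[pos] + rng.integers(1, 4, size=k)) % 4
        return out

    with pysam.AlignmentFile(str(unsorted_bam), "wb", header=header) as bam:
        for i in range(len(pair_mol)):
            qname = f"sim{i:08d}"
            barcode = f"BX{mol_barcode[pair_mol[i]]:08d}"
            specs = []
            for mate, (s, e, r0, pre, suf, is_map, rev) in enumerate(
                [
                    (a_start[i], a_end[i], a_ref[i], a_pre[i], a_suf[i], a_mapped[i], False),
                    (b_start[i], b_end[i], b_ref[i], b_pre[i], b_suf[i], b_mapped[i], True),
                ]
            ):
                enc = _mutate(donor_enc[s:e], int(err_counts[2 * i + mate]))
                specs.append((decode(enc), int(r0), int(pre), int(suf), bool(is_map), rev))
            for mate in (0, 1):
                seq, r0, pre, suf, is_map, rev = specs[mate]
                oseq, o_r0, _, _, o_map, _ = specs[1 - mate]
                rec = pysam.AlignedSegment(header)
                rec.query_name = qname
                rec.query_sequence = seq
                flag = 0x1  # paired
                is_read1 = (mate == 0) == bool(fwd_is_read1[i])
                flag |= 0x40 if is_read1 else 0x80
                if rev:
                    flag |= 0x10
                if not is_map:
                    flag |= 0x4
                if not o_map:
                    flag |= 0x8
                elif mate == 0:
                    flag |= 0x20  # partner (mate B) is on the reverse strand
                rec.flag = flag
                if is_map:
                    rec.reference_id = 0
                    rec.reference_start = r0
                    rec.mapping_quality = 60
                    if pre and pre < rl:
                        rec.cigartuples = [(_OP_M, pre), (_OP_S, rl - pre)]
                    elif suf and suf < rl:
                        rec.cigartuples = [(_OP_S, rl - suf), (_OP_M, suf)]
                    else:
                        rec.cigartuples = [(_OP_M, rl)]
                elif o_map:
                    # unmapped mate placed at its partner for sort adjacency
                    rec.reference_id = 0
                    rec.reference_start = o_r0
                    rec.mapping_quality = 0
                else:
                    rec.reference_id = -1
                    rec.reference_start = -1
                if o_map:
                    rec.next_reference_id = 0
                    rec.next_reference_start = o_r0
                else:
                    rec.next_reference_id = rec.reference_id
                    rec.next_reference_start = rec.reference_start
                rec.query_qualities = qual
                rec.set_tag("BX", barcode, "Z")
                bam.write(rec)
            if emit_fastq:
                fwd_seq, rev_seq = specs[0][0], revcomp(specs[1][0])
                r1, r2 = (
                    (fwd_seq, rev_seq) if fwd_is_read1[i] else (rev_seq, fwd_seq)
                )
                fq1_fh.write(f"@{qname} BX:Z:{barcode}\n{r1}\n+\n{qual_str}\n")
                fq2_fh.write(f"@{qname} BX:Z:{barcode}\n{r2}\n+\n{qual_str}\n")

    if fq1_fh:
        fq1_fh.close()
        fq2_fh.close()

    pysam.sort("-o", str(truth_bam), str(unsorted_bam))
    unsorted_bam.unlink()
    pysam.index(str(truth_bam))

    return SimulationResult(
        reference_fasta=ref_fa,
        donor_fasta=donor_fa,
        truth_vcf=truth_vcf,
        truth_bam=truth_bam,
        fastq1=fq1,
        fastq2=fq2,
        truth=truth,
        n_pairs=n_pairs,
        n_barcodes=n_barcodes,
    )


def _keep_pair(qname: str, ratio: float, seed: int) -> bool:
    h = zlib.crc32(f"{seed}:{qname}".encode()) & 0xFFFFFFFF
    return h / 2**32 < ratio


def downsample_bam(
    in_path: str | Path, out_path: str | Path, ratio: float, seed: int
) -> tuple[int, int]:
    """Keep each read pair independently with probability ``ratio``.

    Mates are kept or dropped atomically (decision hashes the read id),
    so the same pairs survive regardless of record order or file
    splitting. Returns (pairs_in, pairs_kept) based on read-1 records.
    """
    if not 0.0 < ratio <= 1.0:
        raise ValueError("ratio must be in (0, 1]")
    n_in = n_kept = 0
    with pysam.AlignmentFile(str(in_path), "rb", check_sq=False) as src:
        with pysam.AlignmentFile(str(out_path), "wb", template=src) as dst:
            for rec in src.fetch(until_eof=True):
                if rec.is_read1 and not rec.is_secondary and not rec.is_supplementary:
                    n_in += 1
                if _keep_pair(rec.query_name, ratio, seed):
                    if rec.is_read1 and not rec.is_secondary and not rec.is_supplementary:
                        n_kept += 1
                    dst.write(rec)
    pysam.index(str(out_path))
    return n_in, n_kept


def downsample_fastq_pair(
    in1: str | Path,
    in2: str | Path,
    out1: str | Path,
    out2: str | Path,
    ratio: float,
    seed: int,
) -> tuple[int, int]:
    """FASTQ twin of :func:`downsample_bam` (keeps 4-line records verbatim)."""
    if not 0.0 < ratio <= 1.0:
        raise ValueError("ratio must be in (0, 1]")
    n_in = n_kept = 0
    with open(in1) as f1, open(in2) as f2, open(out1, "w") as o1, open(out2, "w") as o2:
        while True:
            block1 = [f1.readline() for _ in range(4)]
            block2 = [f2.readline() for _ in range(4)]
            if not block1[0]:
                break
            n_in += 1
            qname = block1[0][1:].split()[0]
            if _keep_pair(qname, ratio, seed):
                n_kept += 1
                o1.writelines(block1)
                o2.writelines(block2)
    return n_in, n_kept


def molecule_stats(
    bam_path: str | Path,
    max_intra_barcode_gap: int = 50_000,
    barcode_tag: str = "BX",
) -> list[MoleculeStat]:
    """Per-barcode molecule spans and coverages from a sorted BAM.

    Reads of one barcode on one chromosome are split into molecules
    wherever consecutive alignment starts are more than
    ``max_intra_barcode_gap`` apart; molecule length is the span from
    leftmost start to rightmost end and coverage is aligned bases over
    that span.
    """
    per_bc: dict[tuple[str, str], list[tuple[int, int]]] = {}
    with pysam.AlignmentFile(str(bam_path), "rb", check_sq=False) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if not rec.has_tag(barcode_tag):
                continue
            key = (rec.get_tag(barcode_tag), rec.reference_name)
            per_bc.setdefault(key, []).append(
                (rec.reference_start, rec.reference_end)
            )
    out: list[MoleculeStat] = []
    for (barcode, chrom), spans in per_bc.items():
        spans.sort()
        cluster: list[tuple[int, int]] = []
        for span in spans:
            if cluster and span[0] - cluster[-1][0] > max_intra_barcode_gap:
                out.append(_molecule_from_cluster(barcode, chrom, cluster))
                cluster = []
            cluster.append(span)
        if cluster:
            out.append(_molecule_from_cluster(barcode, chrom, cluster))
    out.sort(key=lambda m: (m.chrom, m.start, m.barcode))
    return out


def _molecule_from_cluster(
    barcode: str, chrom: str, cluster: list[tuple[int, int]]
) -> MoleculeStat:
    start = min(s for s, _ in cluster)
    end = max(e for _, e in cluster)
    aligned = sum(e - s for s, e in cluster)
    length = end - start
    return MoleculeStat(
        barcode=barcode,
        chrom=chrom,
        start=start,
        end=end,
        molecule_length=length,
        molecule_coverage=aligned / length if length else 0.0,
    )


def load_truth_vcf(path: str | Path) -> TruthSet:
    """Read a truth VCF back into a TruthSet (POS is the 1-based left base)."""
    from .io_formats import read_vcf

    return TruthSet(
        [
            TruthRecord(rec.chrom, rec.pos - 1, rec.alt_allele[1:])
            for rec in read_vcf(path)
        ]
    )
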