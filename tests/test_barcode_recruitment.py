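import numpy as np
import pytest

from conftest import ReadSpec
from nrscall._dna import random_dna, revcomp
from nrscall.barcode_recruitment import (
    BarcodeList,
    RecruitmentParams,
    build_barcode_lists,
    fetch_reads_by_barcodes,
    filter_contig_alignment,
    reassemble_and_match,
)
from nrscall.dbg_assembler import AssemblyParams, Contig
from nrscall.pairwise_align import LocalAlignment, TargetIndex, seed_and_extend
from nrscall.read_extraction import ExtractedPair, UnalignedSet


def make_aln(qs, qe, mapq=60):
    return LocalAlignment("r", "c", qs, qe, 0, qe - qs, "+", qe - qs, 1.0, proxy_mapq=mapq)


class TestFilterContigAlignment:
    def test_full_length_kept(self):
        assert filter_contig_alignment(make_aln(0, 100), 100, RecruitmentParams())

    def test_quarter_clipped_dropped(self):
        assert not filter_contig_alignment(make_aln(0, 75), 100, RecruitmentParams())

    def test_boundary_twenty_percent_dropped(self):
        # recruitment uses the inclusive >= 20% rule
        assert not filter_contig_alignment(make_aln(0, 80), 100, RecruitmentParams())
        assert filter_contig_alignment(make_aln(0, 81), 100, RecruitmentParams())

    def test_ambiguous_mapq_dropped(self):
        assert not filter_contig_alignment(make_aln(0, 100, mapq=0), 100, RecruitmentParams())


def _uset_from_reads(reads: list[tuple[str, str | None, str]]) -> UnalignedSet:
    """reads: (read_id, barcode, sequence); mate2 is a dissimilar filler."""
    uset = UnalignedSet()
    filler = random_dna(np.random.default_rng(999), 150)
    for rid, bc, seq in reads:
        uset.pairs.append(
            ExtractedPair(rid, bc, seq, filler, b"%" * len(seq), b"%" * len(filler), "unmapped_end")
        )
    return uset


class TestBuildBarcodeLists:
    def _orphan(self, seed=0, n=600):
        return Contig("orph", random_dna(np.random.default_rng(seed), n), 10.0)

    def test_t_filter_discards(self):
        orphan = self._orphan()
        reads = [
            (f"r{i}", f"B{i}", orphan.sequence[i * 20 : i * 20 + 150]) for i in range(4)
        ]
        blists, rsets = build_barcode_lists([orphan], _uset_from_reads(reads))
        assert blists == {} and rsets == {}

    def test_six_barcodes_retained(self):
        orphan = self._orphan()
        reads = [
            (f"r{i}", f"B{i}", orphan.sequence[i * 20 : i * 20 + 150]) for i in range(6)
        ]
        blists, rsets = build_barcode_lists([orphan], _uset_from_reads(reads))
        assert set(blists) == {"orph"}
        assert len(blists["orph"]) == 6
        assert len(rsets["orph"].read_ids) == 6

    def test_unbarcoded_read_in_r_not_b(self):
        orphan = self._orphan()
        reads = [
            (f"r{i}", f"B{i}", orphan.sequence[i * 20 : i * 20 + 150]) for i in range(5)
        ]
        reads.append(("r_none", None, orphan.sequence[150:300]))
        blists, rsets = build_barcode_lists([orphan], _uset_from_reads(reads))
        assert len(blists["orph"]) == 5
        assert "r_none/1" in rsets["orph"].read_ids

    def test_unrelated_reads_not_recruited(self, rng):
        orphan = self._orphan()
        reads = [(f"r{i}", f"B{i}", random_dna(rng, 150)) for i in range(10)]
        blists, _ = build_barcode_lists([orphan], _uset_from_reads(reads))
        assert blists == {}


class TestFetch:
    def _bam(self, bam_factory):
        specs = []
        for i in range(8):
            bc = "X" if i < 5 else "Y"
            specs.append(ReadSpec(f"p{i}", "A" * 100, flag_read1=True, ref_start=i * 500, barcode=bc))
            specs.append(ReadSpec(f"p{i}", "C" * 100, flag_read1=False, ref_start=i * 500 + 250, barcode=bc))
        specs.append(ReadSpec("p8", "G" * 100, flag_read1=True, ref_start=4000))  # no barcode
        specs.append(ReadSpec("p8", "G" * 100, flag_read1=False, ref_start=4200))
        return bam_factory(specs)

    def test_exhaustive_scan_oracle(self, bam_factory):
        bam = self._bam(bam_factory)
        pools = fetch_reads_by_barcodes(bam, {"c1": BarcodeList("c1", {"X"})})
        assert len(pools["c1"]) == 10  # 5 pairs x 2 mates

    def test_empty_barcode_list_error(self, bam_factory):
        bam = self._bam(bam_factory)
        with pytest.raises(ValueError):
            fetch_reads_by_barcodes(bam, {"c1": BarcodeList("c1", set())})

    def test_shared_barcode_in_both_pools(self, bam_factory):
        bam = self._bam(bam_factory)
        pools = fetch_reads_by_barcodes(
            bam,
            {"c1": BarcodeList("c1", {"X"}), "c2": BarcodeList("c2", {"X", "Y"})},
        )
        assert len(pools["c1"]) == 10
        assert len(pools["c2"]) == 16

    def test_sort_order_independence(self, bam_factory):
        specs = []
        for i in range(6):
            specs.append(ReadSpec(f"p{i}", random_dna(np.random.default_rng(i), 100), flag_read1=True, ref_start=i * 100, barcode="Z"))
            specs.append(ReadSpec(f"p{i}", random_dna(np.random.default_rng(100 + i), 100), flag_read1=False, ref_start=i * 100 + 50, barcode="Z"))
        sorted_bam = bam_factory(specs, sort=True)
        shuffled = list(reversed(specs))
        unsorted_bam = bam_factory(shuffled, sort=False)
        bl = {"c": BarcodeList("c", {"Z"})}
        a = sorted(fetch_reads_by_barcodes(sorted_bam, bl)["c"])
        b = sorted(fetch_reads_by_barcodes(unsorted_bam, bl)["c"])
        assert a == b


class TestReassembleAndMatch:
    def test_insertion_with_anchors(self, rng):
        # reads spanning insertion + flanks reassemble into one anchored contig
        flank_l = random_dna(rng, 1200)
        ins = random_dna(rng, 800)
        flank_r = random_dna(rng, 1200)
        donor = flank_l + ins + flank_r
        pool = [donor[i : i + 150] for i in range(0, len(donor) - 150 + 1, 10)] * 2
        orphan = Contig("orph", ins, 10.0)
        got = reassemble_and_match(
            pool, orphan, AssemblyParams(k=77, coverage_cutoff=3, min_contig_length=200)
        )
        assert got is not None
        seq = got.sequence
        if ins not in seq:
            seq = revcomp(seq)
        assert ins in seq
        left, right = seq.split(ins)
        assert len(left) >= 300 and len(right) >= 300

    def test_degenerate_pool_returns_orphanlike(self, rng):
        ins = random_dna(rng, 700)
        pool = [ins[i : i + 150] for i in range(0, 551, 10)] * 3
        orphan = Contig("orph", ins, 10.0)
        got = reassemble_and_match(
            pool, orphan, AssemblyParams(k=77, coverage_cutoff=3, min_contig_length=200)
        )
        assert got is not None
        assert abs(len(got.sequence) - len(ins)) < 100

    def test_offsite_pollution_removed(self, rng):
        flank_l, ins, flank_r = random_dna(rng, 800), random_dna(rng, 700), random_dna(rng, 800)
        donor = flank_l + ins + flank_r
        pool = [donor[i : i + 150] for i in range(0, len(donor) - 150 + 1, 8)] * 2
        offsite = random_dna(rng, 2000)
        pool += [offsite[i : i + 150] for i in range(0, len(offsite) - 150 + 1, 120)]  # ~1x
        orphan = Contig("orph", ins, 10.0)
        got = reassemble_and_match(
            pool, orphan, AssemblyParams(k=77, coverage_cutoff=3, min_contig_length=200)
        )
        assert got is not None
        for probe_at in (0, 500, 1000, 1500):
            probe = offsite[probe_at : probe_at + 100]
            assert probe not in got.sequence and revcomp(probe) not in got.sequence

    def test_empty_pool_error(self):
        with pytest.raises(ValueError):
            reassemble_and_match([], Contig("o", "A" * 300, 1.0))

    def test_unmatched_pool_returns_none(self, rng):
        pool = [random_dna(rng, 150) for _ in range(20)]
        orphan = Contig("orph", random_dna(rng, 600), 10.0)
        got = reassemble_and_match(
            pool, orphan, AssemblyParams(k=77, coverage_cutoff=0, min_contig_length=100)
        )
        assert got is None


def test_blist_invariants_on_simulated_recruitment(rng):
    # B(c) is always a subset of barcodes present in the input
    orphan_seq = random_dna(rng, 800)
    orphan = Contig("c0", orphan_seq, 5.0)
    barcodes = [f"B{i}" for i in range(8)]
    reads = [
        (f"r{i}", barcodes[i % 8], orphan_seq[(i * 37) % 600 : (i * 37) % 600 + 150])
        for i in range(24)
    ]
    blists, _ = build_barcode_lists([orphan], _uset_from_reads(reads))
    assert blists["c0"].barcodes <= set(barcodes)
    assert len(blists["c0"]) >= RecruitmentParams().min_barcodes
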