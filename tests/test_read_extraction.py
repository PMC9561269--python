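import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ReadSpec
from nrscall.io_formats import AlignedRead
from nrscall.read_extraction import (
    ExtractionThresholds,
    classify_pair,
    clip_fraction,
    extract_unaligned_set,
    mean_base_quality,
)


def make_read(
    cigar=None,
    mapped=True,
    mapq=60,
    quals=None,
    seq_len=100,
    mate=1,
    barcode=None,
):
    seq = "A" * seq_len
    return AlignedRead(
        read_id="r",
        mate_index=mate,
        barcode=barcode,
        is_mapped=mapped,
        is_reverse=False,
        mate_is_mapped=True,
        ref_name="chr1" if mapped else None,
        ref_start=0 if mapped else -1,
        cigar=cigar if cigar is not None else ([("M", seq_len)] if mapped else []),
        mapq=mapq if mapped else 0,
        sequence=seq,
        qualities=quals if quals is not None else [30] * seq_len,
    )


class TestClipFraction:
    def test_full_match(self):
        assert clip_fraction(make_read(cigar=[("M", 100)])) == 0.0

    def test_30s70m(self):
        # oracle: soft-clipped bases / total query bases
        read = make_read(cigar=[("S", 30), ("M", 70)])
        assert clip_fraction(read) == pytest.approx(30 / 100)

    def test_boundary_two_sided(self):
        read = make_read(cigar=[("S", 10), ("M", 80), ("S", 10)])
        assert clip_fraction(read) == pytest.approx(0.20)
        # boundary: exactly 20% is NOT kept by the strict > rule
        pair = (read, make_read())
        keep, reason = classify_pair(pair, ExtractionThresholds())
        assert not keep

    def test_hard_clip_denominator_only(self):
        read = make_read(cigar=[("H", 50), ("M", 50)], seq_len=50)
        assert clip_fraction(read) == 0.0
        read = make_read(cigar=[("H", 50), ("S", 25), ("M", 25)], seq_len=50)
        assert clip_fraction(read) == pytest.approx(0.25)

    def test_unmapped_zero(self):
        assert clip_fraction(make_read(mapped=False)) == 0.0


class TestMeanBaseQuality:
    def test_uniform(self):
        pair = (make_read(quals=[30] * 100), make_read(quals=[30] * 100, mate=2))
        assert mean_base_quality(pair) == 30.0

    def test_pooled_boundary(self):
        pair = (make_read(quals=[10] * 100), make_read(quals=[30] * 100, mate=2))
        assert mean_base_quality(pair) == 20.0
        # unmapped end would keep it, but quality 20.0 is not > 20
        pair = (make_read(mapped=False, quals=[10] * 100), make_read(quals=[30] * 100, mate=2))
        keep, reason = classify_pair(pair, ExtractionThresholds())
        assert not keep and reason == "low_base_quality"

    def test_empty_qualities_rejected(self):
        pair = (make_read(mapped=False, quals=[]), make_read(quals=[], mate=2))
        keep, reason = classify_pair(pair, ExtractionThresholds())
        assert not keep


class TestClassifyPair:
    def test_clean_pair_discarded(self):
        pair = (make_read(quals=[35] * 100), make_read(quals=[35] * 100, mate=2))
        keep, reason = classify_pair(pair, ExtractionThresholds())
        assert not keep and reason == "well_aligned"

    def test_unmapped_end(self):
        pair = (make_read(), make_read(mapped=False, mate=2))
        keep, reason = classify_pair(pair, ExtractionThresholds())
        assert keep and reason == "unmapped_end"

    def test_low_mapq(self):
        pair = (make_read(mapq=5), make_read(mate=2))
        keep, reason = classify_pair(pair, ExtractionThresholds())
        assert keep and reason == "low_mapq"
        # boundary: mapq exactly 10 is not below 10
        pair = (make_read(mapq=10), make_read(mate=2))
        assert not classify_pair(pair, ExtractionThresholds())[0]

    def test_clipped(self):
        pair = (make_read(cigar=[("S", 30), ("M", 70)]), make_read(mate=2))
        keep, reason = classify_pair(pair, ExtractionThresholds())
        assert keep and reason == "clipped"


class TestExtract:
    def _spec_pair(self, qname, keep_kind=None, quals=None):
        q = quals or [30] * 100
        s1 = ReadSpec(qname, "A" * 100, flag_read1=True, ref_start=100, qualities=q, barcode=f"B_{qname}")
        s2 = ReadSpec(qname, "C" * 100, flag_read1=False, ref_start=400, qualities=q, barcode=f"B_{qname}")
        if keep_kind == "unmapped":
            s2.unmapped = True
            s1.mate_unmapped = True
            s2.ref_start = 100
        elif keep_kind == "mapq":
            s1.mapq = 3
        elif keep_kind == "clip":
            s1.cigar = [(4, 30), (0, 70)]
        return [s1, s2]

    def test_clean_bam_empty_u(self, bam_factory):
        specs = list(itertools.chain(*[self._spec_pair(f"p{i}") for i in range(5)]))
        uset = extract_unaligned_set(bam_factory(specs))
        assert len(uset) == 0
        assert uset.n_pairs_seen == 5

    def test_counts_match_per_pair_oracle(self, bam_factory):
        kinds = [None, "unmapped", None, "mapq", "clip", None, None, "unmapped", None, None]
        specs = list(
            itertools.chain(*[self._spec_pair(f"p{i}", k) for i, k in enumerate(kinds)])
        )
        bam = bam_factory(specs)
        uset = extract_unaligned_set(bam)
        assert len(uset) == 4
        kept_ids = {p.read_id for p in uset.pairs}
        assert kept_ids == {"p1", "p3", "p4", "p7"}
        # exhaustive cross-check against classify_pair on AlignedReads
        from nrscall.io_formats import read_alignments

        pairs = {}
        for read in read_alignments(bam):
            pairs.setdefault(read.read_id, {})[read.mate_index] = read
        oracle = {
            rid
            for rid, p in pairs.items()
            if classify_pair((p[1], p[2]), ExtractionThresholds())[0]
        }
        assert kept_ids == oracle
        assert len(uset) + sum(
            uset.counts[r] for r in ("well_aligned", "low_base_quality")
        ) == uset.n_pairs_seen

    def test_barcode_carried(self, bam_factory):
        specs = self._spec_pair("px", "unmapped")
        uset = extract_unaligned_set(bam_factory(specs))
        assert uset.pairs[0].barcode == "B_px"

    def test_order_independence(self, bam_factory):
        kinds = [None, "unmapped", "mapq", None, "clip"]
        specs = list(
            itertools.chain(*[self._spec_pair(f"p{i}", k) for i, k in enumerate(kinds)])
        )
        a = extract_unaligned_set(bam_factory(specs, sort=True))
        b = extract_unaligned_set(bam_factory(list(reversed(specs)), sort=False))
        assert [p.read_id for p in a.pairs] == [p.read_id for p in b.pairs]

    def test_missing_mate_dropped(self, bam_factory):
        specs = self._spec_pair("pa", "unmapped") + self._spec_pair("pb", "unmapped")[:1]
        uset = extract_unaligned_set(bam_factory(specs))
        assert {p.read_id for p in uset.pairs} == {"pa"}
        assert uset.n_unpaired_dropped == 1


class TestMonotonicity:
    @given(
        mapq=st.integers(0, 60),
        clip=st.integers(0, 50),
        qual=st.integers(2, 41),
        min_mapq=st.integers(0, 30),
        max_clip=st.floats(0.0, 0.5),
        min_q=st.floats(2, 40),
    )
    @settings(max_examples=200, deadline=None)
    def test_tightening_never_flips_wrong_way(self, mapq, clip, qual, min_mapq, max_clip, min_q):
        pair = (
            make_read(cigar=[("S", clip), ("M", 100 - clip)], mapq=mapq, quals=[qual] * 100),
            make_read(mate=2, quals=[qual] * 100),
        )
        base = ExtractionThresholds(min_mapq=min_mapq, max_clip_fraction=max_clip, min_mean_base_quality=min_q)
        keep_base = classify_pair(pair, base)[0]
        # raising min_mapq or lowering max_clip_fraction never shrinks U
        wider = ExtractionThresholds(
            min_mapq=min_mapq + 5, max_clip_fraction=max(0.0, max_clip - 0.1), min_mean_base_quality=min_q
        )
        if keep_base:
            assert classify_pair(pair, wider)[0]
        # raising the quality floor never grows U
        stricter_q = ExtractionThresholds(
            min_mapq=min_mapq, max_clip_fraction=max_clip, min_mean_base_quality=min_q + 5
        )
        if not keep_base:
            reason = classify_pair(pair, base)[1]
            if reason == "low_base_quality":
                assert not classify_pair(pair, stricter_q)[0]
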