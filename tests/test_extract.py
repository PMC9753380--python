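"""Fragment statistics, candidate selection and read placement."""

from collections import Counter

import numpy as np
import pysam
import pytest
from hypothesis import given, settings, strategies as st

from strsweep.config import SweepConfig
from strsweep.extract import (EvidenceClass, FragmentStats, InformativeRead,
                              classify_and_place, fragment_stats_from_lengths,
                              read_records, select_candidate_reads,
                              write_records)
from strsweep.kmers import canonical_rotation, representative_unit
from strsweep.sinks import SinkLookup, SinkRegion

CFG = SweepConfig()


class TestFragmentStats:
    def test_uniform_order_statistics(self):
        stats = fragment_stats_from_lengths(range(1, 1001))
        assert abs(stats.median - 500.5) <= 0.5
        assert stats.p98 == 980
        assert stats.n_observations == 1000

    def test_constant_lengths(self):
        stats = fragment_stats_from_lengths([400] * 1500)
        assert stats.median == 400
        assert stats.p98 == 400

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="unusable"):
            fragment_stats_from_lengths([400] * 999)

    def test_simulated_normal_fragments(self, het600_sample):
        """Simulator BAM with Normal(400, 50) fragments recovers the mean."""
        _, _, evidence = het600_sample
        assert abs(evidence.frag.median - 400) <= 5
        assert evidence.frag.p98 > evidence.frag.median


def _seg(name, pos, cigar, mapq=60, unmapped=False, nm=0, header=None):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = "ACGT" * 25
    a.is_paired = True
    if unmapped:
        a.is_unmapped = True
    else:
        a.reference_id = 0
        a.reference_start = pos
        a.cigarstring = cigar
        a.mapping_quality = mapq
        a.set_tag("NM", nm)
    return a


@pytest.fixture()
def toy_bam(tmp_path):
    """Hand-built BAM exercising every candidate-selection branch."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"},
         "SQ": [{"SN": "c1", "LN": 100_000}]})
    reads = [
        _seg("perfect_nonsink", 1000, "100M", header=header),
        _seg("in_sink", 50_000, "100M", header=header),
        _seg("low_mapq", 2000, "100M", mapq=10, header=header),
        _seg("soft_clipped", 3000, "60M40S", header=header),
        _seg("mismatched", 4000, "100M", nm=2, header=header),
        _seg("unmapped_read", 0, "", unmapped=True, header=header),
    ]
    path = tmp_path / "toy.bam"
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for r in sorted(reads, key=lambda x: x.reference_start if not x.is_unmapped else 1 << 40):
            bam.write(r)
    pysam.index(str(path))
    return path


def test_select_candidate_reads_branches(toy_bam):
    sinks = SinkLookup([SinkRegion("c1", 49_900, 50_200, "AGC")])
    with pysam.AlignmentFile(toy_bam) as bam:
        names = {r.query_name for r in select_candidate_reads(bam, sinks, CFG)}
    assert names == {"in_sink", "low_mapq", "soft_clipped", "mismatched",
                     "unmapped_read"}


FRAG = FragmentStats(median=400, p98=500, n_observations=10_000)
HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6"}, "SQ": [{"SN": "c1", "LN": 100_000}]})


def _pair(mate_pos, mate_reverse=False, str_seq="AAG" * 50, mate_seq=None,
          mate_mapq=60):
    """(STR read, mapped mate) with controllable mate geometry."""
    rng = np.random.default_rng(1)
    mate_seq = mate_seq or "".join(rng.choice(list("ACGT"), size=150))
    str_read = pysam.AlignedSegment(HEADER)
    str_read.query_name = "t"
    str_read.query_sequence = str_seq
    str_read.is_paired = True
    str_read.is_read1 = True
    str_read.is_unmapped = True
    mate = pysam.AlignedSegment(HEADER)
    mate.query_name = "t"
    mate.query_sequence = mate_seq
    mate.is_paired = True
    mate.is_read2 = True
    mate.reference_id = 0
    mate.reference_start = mate_pos
    mate.cigarstring = "150M"
    mate.mapping_quality = mate_mapq
    mate.is_reverse = mate_reverse
    return str_read, mate


class TestClassifyAndPlace:
    def test_forward_mate_anchors_downstream(self):
        str_read, mate = _pair(2000)
        p1 = representative_unit(str_read.query_sequence)
        p2 = representative_unit(mate.query_sequence)
        recs = classify_and_place((str_read, mate), p1, p2, FRAG, CFG,
                                  sample="s")
        assert len(recs) == 1
        rec = recs[0]
        assert rec.evidence_class is EvidenceClass.ANCHORED
        assert rec.chrom == "c1" and rec.position == 2400
        assert rec.unit == canonical_rotation("AAG")
        assert rec.repeat_count == 50

    def test_reverse_mate_anchors_upstream(self):
        str_read, mate = _pair(5000, mate_reverse=True)
        p1 = representative_unit(str_read.query_sequence)
        p2 = representative_unit(mate.query_sequence)
        recs = classify_and_place((str_read, mate), p1, p2, FRAG, CFG)
        assert recs[0].evidence_class is EvidenceClass.ANCHORED
        assert recs[0].position == 5150 - 400  # mate outer end - median

    def test_both_repetitive_single_unplaced(self):
        str_read, mate = _pair(2000, str_seq="CGG" * 50, mate_seq="CGG" * 50)
        p1 = representative_unit(str_read.query_sequence)
        p2 = representative_unit(mate.query_sequence)
        recs = classify_and_place((str_read, mate), p1, p2, FRAG, CFG)
        assert len(recs) == 1
        assert recs[0].evidence_class is EvidenceClass.UNPLACED
        assert recs[0].chrom is None and recs[0].position is None
        assert recs[0].unit == canonical_rotation("CGG")

    def test_poorly_mapped_mate_gives_unplaced(self):
        str_read, mate = _pair(2000, mate_mapq=5)
        p1 = representative_unit(str_read.query_sequence)
        p2 = representative_unit(mate.query_sequence)
        recs = classify_and_place((str_read, mate), p1, p2, FRAG, CFG)
        assert recs[0].evidence_class is EvidenceClass.UNPLACED

    def test_mate_in_sink_not_an_anchor(self):
        str_read, mate = _pair(2000)
        sinks = SinkLookup([SinkRegion("c1", 1900, 2300, "AT")])
        p1 = representative_unit(str_read.query_sequence)
        p2 = representative_unit(mate.query_sequence)
        recs = classify_and_place((str_read, mate), p1, p2, FRAG, CFG,
                                  sinks=sinks)
        assert recs[0].evidence_class is EvidenceClass.UNPLACED

    def test_clip_record_at_right_clip_coordinate(self):
        read = pysam.AlignedSegment(HEADER)
        read.query_name = "c"
        read.query_sequence = "ACGTA" * 22 + "CAG" * 14  # 110M + 42 bp clip
        read.is_paired = True
        read.is_read1 = True
        read.reference_id = 0
        read.reference_start = 1000
        read.cigarstring = "110M42S"
        read.mapping_quality = 60
        prof = representative_unit(read.query_sequence)
        recs = classify_and_place((read, None), prof, None, FRAG, CFG)
        clips = [r for r in recs if r.evidence_class is EvidenceClass.CLIP_RIGHT]
        assert len(clips) == 1
        assert clips[0].split_position == 1110
        assert clips[0].unit == canonical_rotation("CAG")

    def test_short_clip_ignored(self):
        read = pysam.AlignedSegment(HEADER)
        read.query_name = "c"
        read.query_sequence = "ACGTA" * 29 + "CAGCA"  # 5 bp clip < min_clip_len
        read.is_paired = True
        read.reference_id = 0
        read.reference_start = 1000
        read.cigarstring = "145M5S"
        read.mapping_quality = 60
        recs = classify_and_place((read, None), None, None, FRAG, CFG)
        assert recs == []

    def test_noninformative_pair_empty(self):
        str_read, mate = _pair(2000, str_seq="".join(
            np.random.default_rng(3).choice(list("ACGT"), size=150)))
        p1 = representative_unit(str_read.query_sequence)
        p2 = representative_unit(mate.query_sequence)
        assert classify_and_place((str_read, mate), p1, p2, FRAG, CFG) == []


def test_each_template_one_pair_record(het600_sample):
    """No template contributes both an ANCHORED and an UNPLACED record,
    and pair records never exceed candidate pair count."""
    _, _, evidence = het600_sample
    by_class = Counter(r.evidence_class for r in evidence.records)
    assert by_class[EvidenceClass.ANCHORED] + by_class[EvidenceClass.UNPLACED] \
        <= len(evidence.records)
    assert by_class[EvidenceClass.ANCHORED] > 0
    assert by_class[EvidenceClass.UNPLACED] > 0


def test_anchored_positions_near_true_locus(het600_sample):
    """Every anchored record lies within p98 + 100 bp of the planted locus."""
    truth, _, evidence = het600_sample
    t0, t1 = truth.truth_interval
    slack = evidence.frag.p98 + 100
    for rec in evidence.records:
        if rec.evidence_class is EvidenceClass.ANCHORED:
            assert t0 - slack <= rec.position <= t1 + slack


record_strategy = st.builds(
    InformativeRead,
    sample=st.just("s1"),
    chrom=st.just("c1"),
    position=st.integers(0, 10**6),
    unit=st.sampled_from(["A", "AT", "AAG", "AGC", "AAGGG"]),
    evidence_class=st.sampled_from([EvidenceClass.ANCHORED,
                                    EvidenceClass.CLIP_LEFT,
                                    EvidenceClass.CLIP_RIGHT]),
    repeat_count=st.integers(0, 100),
    split_position=st.none() | st.integers(0, 10**6),
)


class TestRecordIO:
    def test_empty_roundtrip(self, tmp_path):
        path = tmp_path / "empty.str.tsv.gz"
        write_records([], path)
        assert read_records(path) == []

    @given(st.lists(record_strategy, max_size=50))
    @settings(derandomize=True, max_examples=50)
    def test_roundtrip_lossless(self, tmp_path_factory, records):
        path = tmp_path_factory.mktemp("io") / "r.str.tsv.gz"
        unplaced = InformativeRead("s1", None, None, "AGC",
                                   EvidenceClass.UNPLACED, 7)
        records = records + [unplaced]
        write_records(records, path)
        back = read_records(path)
        assert sorted(map(repr, back)) == sorted(map(repr, records))

    def test_unplaced_serializes_with_sentinels(self, tmp_path):
        import gzip

        path = tmp_path / "u.str.tsv.gz"
        write_records([InformativeRead("s1", None, None, "AGC",
                                       EvidenceClass.UNPLACED, 3)], path)
        line = gzip.open(path, "rt").readlines()[1].split("\t")
        assert line[1] == "." and line[2] == "."

    def test_malformed_line_reports_lineno(self, tmp_path):
        import gzip

        path = tmp_path / "bad.str.tsv.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("sample\tchrom\tposition\tunit\tclass\trepeat_count\tsplit_position\n")
            fh.write("s1\tc1\tnot_an_int\tAGC\tANCHORED\t3\t.\n")
        with pytest.raises(ValueError, match=":2"):
            read_records(path)
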