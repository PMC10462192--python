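"""Event data model, format readers/writers and coordinate conventions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from misplice import (
    GenomicInterval,
    SplicingEvent,
    fetch_sequence,
    read_events_table,
    read_gene_sets,
    read_sample_table,
    reverse_complement,
    write_events_table,
    write_sample_table,
)
from misplice.io import ParseError, one_based_to_zero, write_fasta, zero_to_one_based


class TestIntervalAndEvent:
    def test_interval_rejects_bad_coordinates_and_strand(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 5, "*")

    def test_mxe_needs_two_nonoverlapping_exons(self):
        fu = GenomicInterval("c", 0, 100)
        fd = GenomicInterval("c", 900, 1000)
        with pytest.raises(ValueError, match="2 alternative"):
            SplicingEvent("e", "MXE", "g", "G", (GenomicInterval("c", 200, 300),), fu, fd)
        with pytest.raises(ValueError, match="overlap"):
            SplicingEvent(
                "e", "MXE", "g", "G",
                (GenomicInterval("c", 200, 320), GenomicInterval("c", 300, 400)),
                fu, fd,
            )

    def test_flanks_must_bracket_alt_exon_per_strand(self):
        alt = (GenomicInterval("c", 200, 300, "-"),)
        fu = GenomicInterval("c", 0, 100, "-")  # genomically left = downstream on '-'
        fd = GenomicInterval("c", 900, 1000, "-")
        with pytest.raises(ValueError, match="bracket"):
            SplicingEvent("e", "SE", "g", "G", alt, fu, fd)
        ev = SplicingEvent("e", "SE", "g", "G", alt, fd, fu)  # swapped: valid
        assert ev.intron_upstream.start == 300  # abuts exon end on '-'
        assert ev.intron_downstream.end == 200

    @given(st.integers(1, 10**8), st.integers(1, 10**4))
    def test_coordinate_conversion_round_trip(self, start1, length):
        end1 = start1 + length - 1  # 1-based inclusive
        s0, e0 = one_based_to_zero(start1, end1)
        assert e0 - s0 == length
        assert zero_to_one_based(s0, e0) == (start1, end1)


RMATS_SE = """\
ID\tGeneID\tgeneSymbol\tchr\tstrand\texonStart_0base\texonEnd\tupstreamES\tupstreamEE\tdownstreamES\tdownstreamEE\tID\tIJC_SAMPLE_1\tSJC_SAMPLE_1\tIJC_SAMPLE_2\tSJC_SAMPLE_2\tIncFormLen\tSkipFormLen\tPValue\tFDR\tIncLevel1\tIncLevel2\tIncLevelDifference
1\t"g1"\t"Scn2a"\tchr2\t+\t1000\t1012\t500\t650\t2000\t2150\t1\t30,25,28\t5,NA,3\t10,12\t20,18\t98\t49\t0.01\t0.02\t0.9\t0.4\t0.5
"""

RMATS_A5SS_MINUS = """\
ID\tGeneID\tgeneSymbol\tchr\tstrand\tlongExonStart_0base\tlongExonEnd\tshortES\tshortEE\tflankingES\tflankingEE\tID\tIJC_SAMPLE_1\tSJC_SAMPLE_1\tIJC_SAMPLE_2\tSJC_SAMPLE_2\tIncFormLen\tSkipFormLen\tPValue\tFDR\tIncLevel1\tIncLevel2\tIncLevelDifference
7\tg2\tAnk2\tchr5\t-\t3000\t3200\t3050\t3200\t1000\t1100\t7\t12\t8\t15\t4\t98\t49\t0.5\t0.6\t0.6\t0.7\t-0.1
"""


class TestRmatsDialect:
    def test_se_row_parses_with_0base_coordinates_and_split_counts(self, tmp_path):
        p = tmp_path / "SE.MATS.JC.txt"
        p.write_text(RMATS_SE)
        events, counts = read_events_table(p, "rmats-jc")
        (ev,) = events
        # exonStart_0base/exonEnd pass through unchanged (already 0-based half-open)
        assert (ev.alt_exons[0].start, ev.alt_exons[0].end) == (1000, 1012)
        assert ev.event_type == "SE" and ev.gene_symbol == "SCN2A"
        assert ev.alt_exon_length == 12
        np.testing.assert_array_equal(counts.inclusion[0], [30, 25, 28, 10, 12])
        assert np.isnan(counts.skipping[0, 1])  # NA -> missing, not zero
        np.testing.assert_array_equal(counts.skipping[0, [0, 2, 3, 4]], [5, 3, 20, 18])

    def test_sample_id_arity_mismatch_is_an_error(self, tmp_path):
        p = tmp_path / "SE.MATS.JC.txt"
        p.write_text(RMATS_SE)
        with pytest.raises(ParseError, match="sample ids"):
            read_events_table(p, "rmats-jc", sample_ids=["a", "b"])

    def test_a5ss_minus_strand_alt_region_is_long_minus_short(self, tmp_path):
        p = tmp_path / "A5SS.MATS.JC.txt"
        p.write_text(RMATS_A5SS_MINUS)
        events, _ = read_events_table(p, "rmats-jc", event_type="A5SS")
        (ev,) = events
        assert (ev.alt_exons[0].start, ev.alt_exons[0].end) == (3000, 3050)
        # transcript-upstream flank is the short exon (genomically right on '-')
        assert ev.flank_up.start == 3050
        assert ev.flank_down.start == 1000

    def test_mxe_and_ri_dialects(self, tmp_path):
        mxe = (
            "ID\tGeneID\tgeneSymbol\tchr\tstrand\t1stExonStart_0base\t1stExonEnd\t"
            "2ndExonStart_0base\t2ndExonEnd\tupstreamES\tupstreamEE\tdownstreamES\t"
            "downstreamEE\tID\tIJC_SAMPLE_1\tSJC_SAMPLE_1\tIJC_SAMPLE_2\tSJC_SAMPLE_2\t"
            "IncFormLen\tSkipFormLen\tPValue\tFDR\tIncLevel1\tIncLevel2\tIncLevelDifference\n"
            "3\tg3\tScn2a\tchr2\t+\t1200\t1290\t1500\t1590\t500\t650\t2000\t2150\t3\t"
            "10\t5\t7\t9\t98\t98\t0.5\t0.5\t0.5\t0.5\t0.0\n"
        )
        p = tmp_path / "MXE.MATS.JC.txt"
        p.write_text(mxe)
        (ev,), _ = read_events_table(p, "rmats-jc")
        assert ev.event_type == "MXE" and len(ev.alt_exons) == 2
        assert ev.alt_exons[0].start == 1200 and ev.alt_exons[1].end == 1590

        ri = (
            "ID\tGeneID\tgeneSymbol\tchr\tstrand\triExonStart_0base\triExonEnd\t"
            "upstreamES\tupstreamEE\tdownstreamES\tdownstreamEE\tID\tIJC_SAMPLE_1\t"
            "SJC_SAMPLE_1\tIJC_SAMPLE_2\tSJC_SAMPLE_2\tIncFormLen\tSkipFormLen\t"
            "PValue\tFDR\tIncLevel1\tIncLevel2\tIncLevelDifference\n"
            "4\tg4\tDmd\tchrX\t-\t500\t2150\t500\t650\t2000\t2150\t4\t10\t5\t7\t9\t"
            "147\t49\t0.5\t0.5\t0.5\t0.5\t0.0\n"
        )
        p = tmp_path / "RI.MATS.JC.txt"
        p.write_text(ri)
        (ev,), _ = read_events_table(p, "rmats-jc")
        assert ev.event_type == "RI"
        # the alternative segment is the retained intron between the flanks
        assert (ev.alt_exons[0].start, ev.alt_exons[0].end) == (650, 2000)
        assert ev.flank_up.start == 2000  # '-' strand: transcript-upstream is right

    def test_empty_file_yields_empty_event_list(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        events, counts = read_events_table(p, "rmats-jc")
        assert events == [] and counts is None

    def test_malformed_count_reports_line_number(self, tmp_path):
        p = tmp_path / "SE.MATS.JC.txt"
        p.write_text(RMATS_SE.replace("30,25,28", "30,x,28"))
        with pytest.raises(ParseError, match="line 2"):
            read_events_table(p, "rmats-jc")


class TestNativeRoundTrip:
    def test_write_then_read_is_identity(self, small_dataset, tmp_path):
        p = tmp_path / "events.tsv"
        write_events_table(small_dataset.events, small_dataset.counts, p)
        events2, counts2 = read_events_table(p, "native-tsv")
        assert events2 == small_dataset.events
        assert counts2.sample_ids == small_dataset.counts.sample_ids
        np.testing.assert_array_equal(counts2.inclusion, small_dataset.counts.inclusion)
        np.testing.assert_array_equal(counts2.skipping, small_dataset.counts.skipping)
        np.testing.assert_array_equal(counts2.inc_len, small_dataset.counts.inc_len)


class TestGmt:
    def test_parse_dedup_and_case_normalisation(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text(
            "SFARI_S1\tdesc\tSCN2A\tANK2\n"
            "DUP\td\tANK2\tANK2\n"
            "CASE\td\tank2\tANK2\n"
        )
        gs = read_gene_sets(p)
        assert gs["SFARI_S1"] == {"SCN2A", "ANK2"}
        assert len(gs["DUP"]) == 1
        assert gs["CASE"] == {"ANK2"}

    def test_short_line_is_a_parse_error(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("ONLY_NAME\tdesc\n")
        with pytest.raises(ParseError, match="line 1"):
            read_gene_sets(p)


class TestFetchSequence:
    GENOME = {"chr1": "AACGtacg"}

    def test_plus_strand_uppercased(self):
        iv = GenomicInterval("chr1", 0, 4, "+")
        assert fetch_sequence(self.GENOME, iv) == "AACG"
        assert fetch_sequence(self.GENOME, GenomicInterval("chr1", 4, 8, "+")) == "TACG"

    def test_minus_strand_is_reverse_complement(self):
        iv = GenomicInterval("chr1", 0, 4, "-")
        assert fetch_sequence(self.GENOME, iv) == reverse_complement("AACG") == "CGTT"

    @given(st.integers(0, 4), st.integers(1, 4))
    def test_minus_equals_revcomp_of_plus(self, start, length):
        end = min(start + length, 8)
        if start >= end:
            return
        plus = fetch_sequence(self.GENOME, GenomicInterval("chr1", start, end, "+"))
        minus = fetch_sequence(self.GENOME, GenomicInterval("chr1", start, end, "-"))
        assert minus == reverse_complement(plus)

    def test_errors(self):
        with pytest.raises(KeyError):
            fetch_sequence(self.GENOME, GenomicInterval("chrX", 0, 2))
        with pytest.raises(IndexError):
            fetch_sequence(self.GENOME, GenomicInterval("chr1", 0, 100))

    def test_pyfaidx_backend_matches_dict(self, tmp_path):
        fa = tmp_path / "g.fa"
        write_fasta({"chr1": self.GENOME["chr1"]}, fa)
        import pyfaidx

        genome = pyfaidx.Fasta(str(fa))
        iv = GenomicInterval("chr1", 1, 7, "-")
        assert fetch_sequence(genome, iv) == fetch_sequence(self.GENOME, iv)


def test_sample_table_round_trip(small_dataset, tmp_path):
    p = tmp_path / "samples.tsv"
    write_sample_table(small_dataset.samples, p)
    st2 = read_sample_table(p)
    assert st2.sample_ids == small_dataset.samples.sample_ids
    assert st2.group("case") == small_dataset.samples.group("case")
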