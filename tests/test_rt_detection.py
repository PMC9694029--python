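"""Retrocopy detection: junction matching, intron-coverage scoring,
insertion-site rules, gene-level assembly."""

import pytest

from svascan.annotation import Strand
from svascan.breakend_model import Orient
from svascan.rt_detection import (
    JunctionHit,
    TranscriptIndex,
    TranscriptSide,
    assemble_rt_events,
    detect_rt,
    find_insertion_sites,
    find_junctions,
    score_transcript,
)

from .conftest import bnd_pair, deletion_like, make_tx


@pytest.fixture
def plus_index(three_exon_plus):
    return TranscriptIndex([three_exon_plus])


class TestFindJunctions:
    def test_adjacent_exon_junction(self, plus_index):
        hits = find_junctions([deletion_like("chr1", 200, 301)], plus_index,
                              maxgap=100)
        (h,) = hits
        assert (h.from_exon, h.to_exon, h.transitive) == (1, 2, False)
        assert (h.gap_left, h.gap_right) == (0, 0)

    def test_transitive_junction_skips_exon(self, plus_index):
        # donor of exon 1 joined to acceptor of exon 3: the A<->C pattern
        (h,) = find_junctions([deletion_like("chr1", 200, 501)], plus_index,
                              maxgap=100)
        assert (h.from_exon, h.to_exon, h.transitive) == (1, 3, True)

    def test_gap_just_over_threshold_excluded(self, plus_index):
        # left breakend 101 bp from every boundary
        assert find_junctions([deletion_like("chr1", 99, 301)], plus_index,
                              maxgap=100) == []
        # and inclusive at exactly the threshold
        (h,) = find_junctions([deletion_like("chr1", 100, 301)], plus_index,
                              maxgap=100)
        assert h.gap_left == 100

    def test_orientation_must_be_deletion_like(self, plus_index):
        wrong = bnd_pair("chr1", 200, Orient.LEFT, "chr1", 301, Orient.RIGHT)
        assert find_junctions([wrong], plus_index, maxgap=100) == []
        assert len(find_junctions([wrong], plus_index, maxgap=100,
                                  strict_orientation=False)) == 1

    def test_minus_strand_junction(self, three_exon_minus):
        idx = TranscriptIndex([three_exon_minus])
        # transcript exon 1 = genomic exon 3; the intron between transcript
        # exons 1 and 2 is genomically between exons 2 and 3
        (h,) = find_junctions([deletion_like("chr1", 400, 501)], idx,
                              maxgap=100)
        assert (h.from_exon, h.to_exon) == (1, 2)

    def test_nearest_boundary_tie_goes_to_lower_exon(self):
        # donors at 200 and 400; breakend at 300 is equidistant
        tx = make_tx(3, start=101, exon_len=100, intron_len=100)
        idx = TranscriptIndex([tx])
        (h,) = find_junctions([deletion_like("chr1", 300, 501)], idx,
                              maxgap=100)
        assert h.from_exon == 1

    def test_interchromosomal_never_matches(self, plus_index):
        bp = bnd_pair("chr1", 200, Orient.RIGHT, "chr2", 301, Orient.LEFT)
        assert find_junctions([bp], plus_index, maxgap=100) == []


class TestScoreTranscript:
    def _hits(self, pairs, tx_id="TXN"):
        return [JunctionHit(breakpoint=None, tx_id=tx_id, from_exon=i,
                            to_exon=j, gap_left=0, gap_right=0)
                for i, j in pairs]

    def test_full_recovery(self):
        tx = make_tx(4)
        assert score_transcript(self._hits([(1, 2), (2, 3), (3, 4)]), tx) == 1.0

    def test_partial_recovery(self):
        tx = make_tx(4)
        assert score_transcript(self._hits([(1, 2)]), tx) == pytest.approx(1 / 3)

    def test_transitive_covers_spanned_introns(self):
        tx = make_tx(4)
        assert score_transcript(self._hits([(1, 4)]), tx) == 1.0

    def test_count_mode_counts_calls_not_introns(self):
        tx = make_tx(4)
        assert score_transcript(self._hits([(1, 4)]), tx, mode="count") == \
            pytest.approx(1 / 3)

    def test_no_double_counting(self):
        tx = make_tx(4)
        assert score_transcript(self._hits([(1, 2), (1, 2), (1, 3)]), tx) == \
            pytest.approx(2 / 3)

    def test_single_exon_undefined(self):
        with pytest.raises(ValueError):
            score_transcript([], make_tx(1))


class TestInsertionSites:
    def test_three_prime_site_on_other_chromosome(self, plus_index):
        bp = bnd_pair("chr1", 600, Orient.RIGHT, "chr2", 70_000, Orient.LEFT)
        (s,) = find_insertion_sites([bp], plus_index)
        assert s.transcript_side is TranscriptSide.THREE_PRIME
        assert s.target_breakend.chrom == "chr2"

    def test_five_prime_site(self, plus_index):
        bp = bnd_pair("chr1", 101, Orient.LEFT, "chr2", 70_000, Orient.RIGHT)
        (s,) = find_insertion_sites([bp], plus_index)
        assert s.transcript_side is TranscriptSide.FIVE_PRIME

    def test_five_prime_flips_with_strand(self, three_exon_minus):
        idx = TranscriptIndex([three_exon_minus])
        bp = bnd_pair("chr1", 600, Orient.RIGHT, "chr2", 70_000, Orient.LEFT)
        (s,) = find_insertion_sites([bp], idx)
        assert s.transcript_side is TranscriptSide.FIVE_PRIME

    def test_both_ends_exonic_is_not_a_site(self, plus_index):
        bp = deletion_like("chr1", 150, 350)
        assert find_insertion_sites([bp], plus_index) == []

    def test_mate_in_own_intron_excluded(self, plus_index):
        bp = deletion_like("chr1", 150, 250)  # 250 is intronic, same locus
        assert find_insertion_sites([bp], plus_index) == []

    def test_mate_within_locus_pad_excluded(self, three_exon_plus):
        idx = TranscriptIndex([three_exon_plus], locus_pad=1000)
        bp = deletion_like("chr1", 150, 1400)  # 1400 within 600+1000
        assert find_insertion_sites([bp], idx) == []
        far = deletion_like("chr1", 150, 1700)
        assert len(find_insertion_sites([far], idx)) == 1


class TestAssemble:
    def test_junctions_only_event_retained(self, three_exon_plus):
        idx = TranscriptIndex([three_exon_plus])
        junctions = find_junctions([deletion_like("chr1", 200, 301)], idx,
                                   maxgap=100)
        (ev,) = assemble_rt_events(junctions, [], idx, minscore=0.4)
        assert ev.insertion_sites == []
        assert ev.tx_scores["TX1"] == pytest.approx(0.5)
        assert ev.passing_transcripts == {"TX1"}

    def test_minscore_excludes_low_coverage(self, three_exon_plus):
        idx = TranscriptIndex([three_exon_plus])
        junctions = find_junctions([deletion_like("chr1", 200, 301)], idx,
                                   maxgap=100)
        (ev,) = assemble_rt_events(junctions, [], idx, minscore=0.6)
        assert ev.passing_transcripts == set()

    def test_two_genes_no_cross_contamination(self):
        tx_a = make_tx(3, start=1001, tx_id="TA", gene_id="GA")
        tx_b = make_tx(3, start=50_001, tx_id="TB", gene_id="GB")
        idx = TranscriptIndex([tx_a, tx_b])
        bps = [deletion_like("chr1", 1100, 1201, stem="a"),
               deletion_like("chr1", 50_100, 50_201, stem="b")]
        events = detect_rt(bps, [tx_a, tx_b])
        assert sorted(ev.gene_id for ev in events) == ["GA", "GB"]
        for ev in events:
            assert all(h.tx_id.startswith("T" + ev.gene_id[-1])
                       for h in ev.junctions)

    def test_single_exon_requires_bracketing_sites(self):
        tx = make_tx(1, start=10_001, tx_id="TS", gene_id="GS")
        idx = TranscriptIndex([tx])
        # exon (10001,10100); midpoint 10050.5
        left = bnd_pair("chr1", 10_010, Orient.LEFT, "chr2", 90_000,
                        Orient.RIGHT, stem="l")
        right = bnd_pair("chr1", 10_090, Orient.RIGHT, "chr2", 90_120,
                         Orient.LEFT, stem="r")
        sites = find_insertion_sites([left, right], idx)
        (ev,) = assemble_rt_events([], sites, idx)
        assert ev.single_exon_only
        assert len(ev.insertion_sites) == 2
        # one side alone is not reported
        one_side = find_insertion_sites([left], idx)
        assert assemble_rt_events([], one_side, idx) == []


class TestMonotonicity:
    def test_raising_minscore_never_adds_passing(self, three_exon_plus):
        idx = TranscriptIndex([three_exon_plus])
        junctions = find_junctions([deletion_like("chr1", 200, 301)], idx,
                                   maxgap=100)
        prev = None
        for minscore in (0.0, 0.25, 0.5, 0.75, 1.0):
            (ev,) = assemble_rt_events(junctions, [], idx, minscore=minscore)
            if prev is not None:
                assert ev.passing_transcripts <= prev
            prev = ev.passing_transcripts

    def test_raising_maxgap_never_removes_hits(self, plus_index):
        bps = [deletion_like("chr1", 200 - d, 301 + d, stem=f"d{d}")
               for d in (0, 10, 60, 99)]
        prev: set = set()
        for maxgap in (0, 10, 50, 100, 200):
            got = {(h.breakpoint.left.record_id, h.from_exon, h.to_exon)
                   for h in find_junctions(bps, plus_index, maxgap=maxgap)}
            assert got >= prev
            prev = got
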