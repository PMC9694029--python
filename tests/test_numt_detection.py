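"""NUMT detection: mito-breakend discovery, insertion realignment with a
circular genome, known-NUMT rescue, site linking, confidence tiers."""

import itertools

import numpy as np
import pytest

from svascan.annotation import RegionSet
from svascan.breakend_model import (
    Breakend,
    InsertionRecord,
    Orient,
    reverse_complement,
)
from svascan.numt_detection import (
    Confidence,
    Evidence,
    MtAligner,
    MtFusionCandidate,
    NUMTEvent,
    assign_confidence,
    find_mt_breakpoints,
    link_sites,
    realign_insertions,
    rescue_known_numt,
)
from svascan.synthetic_data import make_reference

from .conftest import bnd_pair


@pytest.fixture(scope="module")
def mt_seq():
    return make_reference(7, 1000, 16_569)["chrM"]


class TestFindMtBreakpoints:
    def test_translocation_to_chrm(self):
        bp = bnd_pair("chr1", 5000, Orient.RIGHT, "chrM", 2100, Orient.LEFT)
        (c,) = find_mt_breakpoints([bp])
        assert (c.nuclear_chrom, c.nuclear_pos) == ("chr1", 5000)
        assert (c.mt_start, c.mt_end) == (2100, 2100)
        assert c.evidence is Evidence.DIRECT_BND

    def test_intra_mito_excluded_and_counted(self):
        bp = bnd_pair("chrM", 100, Orient.RIGHT, "chrM", 16_000, Orient.LEFT)
        diag = {}
        assert find_mt_breakpoints([bp], diagnostics=diag) == []
        assert diag["intra_mt"] == 1

    def test_mt_alias_recognised(self):
        bp = bnd_pair("chr1", 5000, Orient.RIGHT, "MT", 2100, Orient.LEFT)
        assert len(find_mt_breakpoints([bp])) == 1


class TestRealignment:
    def _rec(self, seq, pos=1000):
        return InsertionRecord(chrom="chr1", pos=pos, seq=seq, record_id="i")

    def test_exact_substring_scores_one(self, mt_seq):
        (c,) = realign_insertions([self._rec(mt_seq[500:600])], mt_seq,
                                  min_len=8, min_align=1.0)
        assert c.align_score_norm == 1.0
        assert (c.mt_start, c.mt_end) == (501, 600)

    def test_short_sequence_discarded_before_alignment(self, mt_seq):
        assert realign_insertions([self._rec(mt_seq[100:107])], mt_seq,
                                  min_len=8, min_align=0.0) == []
        assert len(realign_insertions([self._rec(mt_seq[100:108])], mt_seq,
                                      min_len=8, min_align=0.7)) == 1

    def test_origin_spanning_sequence_full_score(self, mt_seq):
        query = mt_seq[-50:] + mt_seq[:50]
        (c,) = realign_insertions([self._rec(query)], mt_seq,
                                  min_len=8, min_align=0.9)
        assert c.align_score_norm == 1.0
        assert c.mt_start == len(mt_seq) - 49 and c.mt_end == 50

    def test_reverse_strand_integration(self, mt_seq):
        (c,) = realign_insertions([self._rec(reverse_complement(mt_seq[200:300]))],
                                  mt_seq, min_len=8, min_align=0.9)
        assert c.align_score_norm == 1.0

    def test_polya_tail_does_not_depress_score(self, mt_seq):
        (c,) = realign_insertions([self._rec(mt_seq[500:530] + "A" * 20)],
                                  mt_seq, min_len=8, min_align=0.9)
        assert c.align_score_norm == 1.0

    def test_single_breakend_with_sequence_accepted(self, mt_seq):
        sb = Breakend(record_id="s", chrom="chr1", pos=1234,
                      orient=Orient.RIGHT, inserted_seq=mt_seq[40:140])
        (c,) = realign_insertions([sb], mt_seq, min_len=8, min_align=0.9)
        assert c.nuclear_pos == 1234 and c.nuclear_orient is Orient.RIGHT

    def test_random_sequence_scores_below_threshold(self, mt_seq):
        rng = np.random.default_rng(11)
        aligner = MtAligner(mt_seq)
        for _ in range(50):
            q = "".join(rng.permutation(list(mt_seq[3000:3060])))
            assert aligner.normalized_score(q) < 0.7


class TestKnownNumtRescue:
    regions = RegionSet("numts", {"chr5": [(10_000, 10_500)]})

    def test_mate_inside_region_rescued(self):
        bp = bnd_pair("chr1", 777, Orient.RIGHT, "chr5", 10_200, Orient.LEFT)
        (c,) = rescue_known_numt([bp], self.regions, maxgap_numts=10)
        assert c.evidence is Evidence.KNOWN_NUMT_PROXIMITY
        assert (c.nuclear_chrom, c.nuclear_pos) == ("chr1", 777)
        assert c.mt_start is None

    def test_distance_threshold_exact(self):
        at = bnd_pair("chr1", 777, Orient.RIGHT, "chr5", 10_510, Orient.LEFT)
        over = bnd_pair("chr1", 777, Orient.RIGHT, "chr5", 10_511, Orient.LEFT)
        assert len(rescue_known_numt([at], self.regions, maxgap_numts=10)) == 1
        assert rescue_known_numt([over], self.regions, maxgap_numts=10) == []

    def test_both_mates_in_numt_ambiguous(self):
        bp = bnd_pair("chr5", 10_100, Orient.RIGHT, "chr5", 10_400, Orient.LEFT)
        diag = {}
        assert rescue_known_numt([bp], self.regions, 10, diagnostics=diag) == []
        assert diag["both_in_numt"] == 1


def _site(pos, orient, chrom="chr1", filt="PASS", evidence=Evidence.DIRECT_BND):
    return MtFusionCandidate(
        source=None, nuclear_chrom=chrom, nuclear_pos=pos,
        nuclear_orient=orient, evidence=evidence, site_filter=filt)


class TestLinkSites:
    def test_facing_sites_within_distance_link(self):
        events = link_sites([_site(10_000, Orient.RIGHT),
                             _site(10_400, Orient.LEFT)], max_ins_dist=1000)
        (ev,) = events
        assert ev.linked and ev.insertion_span == (10_000, 10_400)

    def test_distant_sites_stay_single(self):
        events = link_sites([_site(10_000, Orient.RIGHT),
                             _site(12_000, Orient.LEFT)], max_ins_dist=1000)
        assert [ev.linked for ev in events] == [False, False]

    def test_distance_threshold_exact(self):
        at = link_sites([_site(10_000, Orient.RIGHT),
                         _site(11_000, Orient.LEFT)], max_ins_dist=1000)
        assert at[0].linked
        over = link_sites([_site(10_000, Orient.RIGHT),
                           _site(11_001, Orient.LEFT)], max_ins_dist=1000)
        assert not any(ev.linked for ev in over)

    def test_same_orientation_never_links(self):
        events = link_sites([_site(10_000, Orient.RIGHT),
                             _site(10_100, Orient.RIGHT)], max_ins_dist=1000)
        assert not any(ev.linked for ev in events)

    def test_three_close_sites_nearest_pair_wins(self):
        events = link_sites([_site(10_000, Orient.RIGHT),
                             _site(10_050, Orient.LEFT),
                             _site(10_900, Orient.RIGHT)], max_ins_dist=1000)
        linked = [ev for ev in events if ev.linked]
        singles = [ev for ev in events if not ev.linked]
        assert len(linked) == 1 and len(singles) == 1
        assert linked[0].insertion_span == (10_000, 10_050)
        assert singles[0].sites[0].nuclear_pos == 10_900

    def test_resolved_insertion_is_intrinsically_linked(self):
        (ev,) = link_sites([_site(500, None,
                                  evidence=Evidence.REALIGNED_INSERTION)])
        assert ev.linked and ev.insertion_span == (500, 500)

    @staticmethod
    def _brute_force(sites, max_ins_dist):
        """Enumerate all pairings; return (max pairs, min total distance)."""
        compat = [
            (i, j, abs(sites[i].nuclear_pos - sites[j].nuclear_pos))
            for i, j in itertools.combinations(range(len(sites)), 2)
            if sites[i].nuclear_orient != sites[j].nuclear_orient
            and abs(sites[i].nuclear_pos - sites[j].nuclear_pos) <= max_ins_dist
        ]
        best_key = (0, 0)  # (-n_pairs, total_distance)
        for r in range(len(compat) + 1):
            for combo in itertools.combinations(compat, r):
                used = [k for i, j, _ in combo for k in (i, j)]
                if len(used) != len(set(used)):
                    continue
                key = (-len(combo), sum(d for _, _, d in combo))
                best_key = min(best_key, key)
        return -best_key[0], best_key[1]

    def test_linking_is_minimum_total_distance(self):
        """Exact pairing: on every small instance the linked pairs
        maximise pair count and minimise total distance."""
        rng = np.random.default_rng(5)
        for trial in range(60):
            n = int(rng.integers(2, 7))
            sites = [_site(int(rng.integers(0, 3000)),
                           Orient.RIGHT if rng.random() < 0.5 else Orient.LEFT)
                     for _ in range(n)]
            events = link_sites(sites, max_ins_dist=1000)
            n_pairs = sum(1 for ev in events if ev.linked)
            total = sum(ev.insertion_span[1] - ev.insertion_span[0]
                        for ev in events if ev.linked)
            assert (n_pairs, total) == self._brute_force(sites, 1000), trial

    def test_monotone_in_max_ins_dist(self):
        rng = np.random.default_rng(9)
        sites = [_site(int(rng.integers(0, 5000)),
                       Orient.RIGHT if k % 2 else Orient.LEFT)
                 for k in range(10)]
        prev = -1
        for d in (0, 100, 500, 1000, 5000):
            n_linked = sum(1 for ev in link_sites(sites, max_ins_dist=d)
                           if ev.linked)
            assert n_linked >= prev
            prev = n_linked


class TestConfidence:
    @pytest.mark.parametrize("f1,f2,expected", [
        ("PASS", "PASS", Confidence.HIGH),
        ("PASS", "LOW_QUAL", Confidence.INTERMEDIATE),
        ("LOW_QUAL", "PASS", Confidence.INTERMEDIATE),
        ("LOW_QUAL", "LOW_QUAL", Confidence.LOW),
    ])
    def test_linked_event_tiers(self, f1, f2, expected):
        ev = NUMTEvent(nuclear_chrom="chr1",
                       sites=[_site(100, Orient.RIGHT, filt=f1),
                              _site(200, Orient.LEFT, filt=f2)],
                       linked=True)
        assert assign_confidence(ev) is expected

    @pytest.mark.parametrize("f,expected", [
        ("PASS", Confidence.INTERMEDIATE),
        ("LOW_QUAL", Confidence.LOW),
    ])
    def test_single_site_tiers(self, f, expected):
        ev = NUMTEvent(nuclear_chrom="chr1",
                       sites=[_site(100, Orient.RIGHT, filt=f)], linked=False)
        assert assign_confidence(ev) is expected


class TestMonotonicity:
    def test_thresholds_never_add_candidates(self, mt_seq):
        recs = [InsertionRecord(chrom="chr1", pos=100 * (k + 1),
                                seq=mt_seq[k * 200:k * 200 + 30 + 10 * k],
                                record_id=f"i{k}")
                for k in range(6)]
        prev = None
        for min_len in (10, 30, 50, 80):
            n = len(realign_insertions(recs, mt_seq, min_len=min_len,
                                       min_align=0.7))
            if prev is not None:
                assert n <= prev
            prev = n
        prev = None
        for min_align in (0.5, 0.7, 0.9, 1.0):
            n = len(realign_insertions(recs, mt_seq, min_len=8,
                                       min_align=min_align))
            if prev is not None:
                assert n <= prev
            prev = n
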