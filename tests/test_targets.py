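"""ORF/UTR extraction and accessibility-energy target scoring."""

import random

import pytest

from coralmir.formats import SeqRecord, revcomp
from coralmir.targets import (
    EnergyModel,
    UTR3,
    duplex_dG,
    extract_utr3,
    longest_orf,
    open_cost,
    predict_targets,
    seed_matches,
)


class TestLongestORF:
    def test_hand_checked_frame_scan(self):
        orf = longest_orf(SeqRecord("t", "AAATGGCCTAAGG"))
        assert (orf.start, orf.end) == (2, 11)
        assert orf.length == 9 and orf.stop_terminated

    def test_no_atg_gives_none(self):
        assert longest_orf(SeqRecord("t", "CCCCCC")) is None

    def test_tie_broken_toward_five_prime(self):
        # two 6-nt ORFs in different frames; the 5'-most wins
        seq = "ATGAAATAGTATGAAATAGT"
        orf = longest_orf(SeqRecord("t", seq))
        assert orf.start == 0

    def test_end_truncated_orf(self):
        orf = longest_orf(SeqRecord("t", "CCATGAAACCC"))
        assert orf.start == 2 and not orf.stop_terminated


class TestUTRExtraction:
    def test_long_utr_kept(self):
        seq = "ATG" + "AAA" * 10 + "TAA" + "C" * 150
        utr = extract_utr3(SeqRecord("t", seq), longest_orf(SeqRecord("t", seq)))
        assert utr is not None and len(utr) == 150

    def test_99bp_utr_filtered_out(self):
        seq = "ATG" + "AAA" * 10 + "TAA" + "C" * 99
        assert extract_utr3(SeqRecord("t", seq),
                            longest_orf(SeqRecord("t", seq))) is None

    def test_exactly_100bp_kept(self):
        seq = "ATG" + "AAA" * 10 + "TAA" + "C" * 100
        assert extract_utr3(SeqRecord("t", seq),
                            longest_orf(SeqRecord("t", seq))) is not None

    def test_no_orf_gives_none(self):
        assert extract_utr3(SeqRecord("t", "CCCC"), None) is None


class TestSeedMatches:
    def test_published_mature_seed_reverse_complement(self):
        mature = "acccguagauccgaacuugugg"
        utr = UTR3("t", "A" * 30 + "CTACGGG" + "A" * 70)
        assert seed_matches(mature, utr) == [30]

    def test_no_match(self):
        assert seed_matches("acccguagauccgaacuugugg",
                            UTR3("t", "A" * 120)) == []

    def test_gu_wobble_flag(self):
        mature = "ACCCGTAGATCCGAACTTGTGG"   # seed CCCGTAG
        # G:U partner for the seed's G at miRNA position 5: T in place of C
        site_wc = revcomp("CCCGTAG")
        site_gu = site_wc.replace("C", "T", 1)
        utr = UTR3("t", "A" * 20 + site_gu + "A" * 80)
        assert seed_matches(mature, utr) == []
        assert seed_matches(mature, utr, allow_gu=True) == [20]


class TestDuplexEnergy:
    def test_seed_only_energy(self):
        mature = "ACCCGTAGATCCGAACTTGTGG"   # seed CCCGTAG: 5 GC + 2 AU
        utr = UTR3("t", "A" * 30 + revcomp("CCCGTAG") + "A" * 70)
        # flanking As cannot pair the adjacent mature bases (A/T-A, G-A)
        assert duplex_dG(mature.lower(), utr, 30) == pytest.approx(-19.0)

    def test_full_complement_energy(self):
        mature = "GCGCGCGCGCATATATATATAT"   # 10 GC + 12 AU pairs
        utr = UTR3("t", "C" * 40 + revcomp(mature) + "C" * 40)
        site = 40 + len(mature) - 8
        assert duplex_dG(mature, utr, site) == pytest.approx(-(10 * 3 + 12 * 2))

    def test_extension_stops_at_first_mismatch(self):
        mature = "ACCCGTAGATCCGAACTTGTGG"
        seed_site = revcomp(mature[1:8])
        # UTR continues with bases complementary to nothing in the mature
        utr = UTR3("t", "A" * 30 + seed_site + "A" * 70)
        seed_only = duplex_dG(mature, utr, 30)
        # extendable context: one extra GC pair on the 3' side of the miRNA
        utr2 = UTR3("t", "A" * 29 + revcomp(mature[8]) + seed_site + "A" * 70)
        assert duplex_dG(mature, utr2, 30) < seed_only


class TestOpenCost:
    def test_unstructured_context_costs_nothing(self):
        utr = UTR3("t", "A" * 50 + "GGGGGGG" + "A" * 50)
        assert open_cost(utr, 50, 57) == 0.0

    def test_five_gc_stem_costs_fifteen(self):
        utr = UTR3("t", "A" * 50 + "GGGGG" + "AAA" + "CCCCC" + "A" * 50)
        assert open_cost(utr, 50, 55) == pytest.approx(15.0)

    def test_adding_pairs_over_the_site_never_decreases_cost(self):
        rng = random.Random(31)
        site_seq = "GGTGTGG"
        for _ in range(20):
            n_stem = rng.randint(0, 7)
            utr_seq = ("A" * 60 + site_seq + "AACAA"
                       + revcomp(site_seq)[:n_stem].rjust(7, "A") + "A" * 50)
            utr_more = ("A" * 60 + site_seq + "AACAA"
                        + revcomp(site_seq)[: min(7, n_stem + 2)].rjust(7, "A")
                        + "A" * 50)
            assert open_cost(UTR3("t", utr_more), 60, 67) >= \
                open_cost(UTR3("t", utr_seq), 60, 67)


class TestPredictTargets:
    def _utrs(self):
        mature = SeqRecord("m1", "ACCCGTAGATCCGAACTTGTGG")
        open_site = UTR3("open", "A" * 50 + revcomp("CCCGTAG") + "A" * 50)
        stem = ("A" * 49 + revcomp("CCCGTAG") + "AACAA" + "CCCGTAG" + "A" * 46)
        stem_site = UTR3("stem", stem)
        return mature, open_site, stem_site

    def test_threshold_retention(self):
        mature, open_site, stem_site = self._utrs()
        sites = predict_targets([mature], [open_site, stem_site], cutoff=-10.0)
        assert [s.transcript_id for s in sites] == ["open"]
        s = sites[0]
        # the open context adds no cost beyond the site's own self-structure
        assert s.dg_duplex == pytest.approx(-19.0)
        assert 0 <= s.open_cost <= 4 and s.ddg <= -10

    def test_stem_occluded_site_dropped(self):
        mature, _, stem_site = self._utrs()
        all_sites = predict_targets([mature], [stem_site], cutoff=-10.0,
                                    keep_all=True)
        assert len(all_sites) == 1
        assert all_sites[0].ddg > -10
        assert all_sites[0].open_cost > 0

    def test_retention_monotone_in_cutoff(self):
        mature, open_site, stem_site = self._utrs()
        utrs = [open_site, stem_site]
        loose = {(s.transcript_id, s.utr_start)
                 for s in predict_targets([mature], utrs, cutoff=0.0)}
        tight = {(s.transcript_id, s.utr_start)
                 for s in predict_targets([mature], utrs, cutoff=-10.0)}
        assert tight <= loose

    def test_ddg_never_below_duplex_energy(self):
        mature, open_site, stem_site = self._utrs()
        for s in predict_targets([mature], [open_site, stem_site], cutoff=0.0,
                                 keep_all=True):
            assert s.open_cost >= 0
            assert s.ddg >= s.dg_duplex
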