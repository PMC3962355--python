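"""Read cleaning: trimming rules, error statistics, adapters, contaminants."""

import math
import random

import pytest

from coralmir.errors import ConfigError, CoralmirError
from coralmir.formats import SeqRecord, SmallRead, revcomp
from coralmir.qc import (
    QCParams,
    composition_table,
    contaminant_filter,
    expected_error_rate,
    passes_all_predicates,
    quality_trim,
    run_qc,
    trim_adapters,
)


def mk(seq, quals=None, rid="r"):
    return SmallRead(rid, seq, quals if quals is not None else [40] * len(seq))


class TestQualityTrim:
    def test_trims_trailing_low_quality_run(self):
        r = quality_trim(mk("ACGTT", [30, 30, 25, 20, 15]))
        assert (r.seq, r.quals) == ("ACG", [30, 30, 25])

    def test_high_quality_read_unchanged(self):
        r = mk("ACG", [40, 40, 40])
        assert quality_trim(r) is r

    def test_all_low_quality_read_empties(self):
        assert len(quality_trim(mk("AC", [10, 5]))) == 0

    def test_idempotent(self):
        rng = random.Random(5)
        for _ in range(100):
            r = mk("A" * 20, [rng.randint(0, 41) for _ in range(20)])
            once = quality_trim(r)
            assert quality_trim(once).seq == once.seq


class TestExpectedErrorRate:
    @pytest.mark.parametrize("quals,expected", [
        ([20] * 7, 0.01),
        ([13] * 10, 10 ** -1.3),
        ([40, 40, 10], (0.0001 + 0.0001 + 0.1) / 3),
    ])
    def test_closed_form_cases(self, quals, expected):
        assert expected_error_rate(mk("A" * len(quals), quals)) == \
            pytest.approx(expected, abs=1e-12)

    def test_matches_per_base_sum_oracle(self):
        rng = random.Random(11)
        for _ in range(1000):
            quals = [rng.randint(0, 93) for _ in range(rng.randint(1, 40))]
            got = expected_error_rate(mk("A" * len(quals), quals))
            oracle = math.fsum(10.0 ** (-q / 10.0) for q in quals) / len(quals)
            assert abs(got - oracle) < 1e-12

    def test_empty_read_is_an_error(self):
        with pytest.raises(CoralmirError):
            expected_error_rate(SmallRead("r", "", []))


ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"


class TestAdapterTrim:
    def test_full_adapter_removed(self):
        insert = "ACGTACGTACGTACGTACGTAC"
        r = trim_adapters(mk(insert + ADAPTER3), ADAPTER3)
        assert r.seq == insert

    def test_minimum_overlap_prefix_removed(self):
        r = trim_adapters(mk("ACGTACGTCCTTACGT" + ADAPTER3[:3]), ADAPTER3)
        assert r.seq == "ACGTACGTCCTTACGT"

    def test_read_without_adapter_unchanged(self):
        r = mk("ACCCTTACCCTTAAT")
        assert trim_adapters(r, ADAPTER3).seq == r.seq

    def test_never_lengthens_and_idempotent(self):
        rng = random.Random(3)
        for _ in range(200):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 40)))
            once = trim_adapters(mk(seq), ADAPTER3)
            assert len(once) <= len(seq)
            assert trim_adapters(once, ADAPTER3).seq == once.seq

    def test_five_prime_adapter_symmetric_rule(self):
        a5 = "GTTCAGAGTTCTACAGTCCGACGATC"
        r = trim_adapters(mk(a5[-5:] + "ACGTACGTCCTTAAG"), "", a5)
        assert r.seq == "ACGTACGTCCTTAAG"


class TestContaminantFilter:
    def test_containment_and_strand_rule(self):
        contam = [SeqRecord("c", "ACGTTGCAACGGTACCTGATCGATC" + "A" * 30)]
        inside = mk(contam[0].seq[2:27], rid="in")
        rc = mk(revcomp(contam[0].seq[5:30]), rid="rc")
        clean = mk("TGCATGCATGCATGCATGCATG", rid="ok")
        kept = contaminant_filter([inside, rc, clean], contam, k=21)
        assert [r.id for r in kept] == ["ok"]

    def test_matches_brute_force_kmer_intersection(self):
        rng = random.Random(21)
        contam = [SeqRecord("c", "".join(rng.choice("ACGT") for _ in range(2000)))]
        reads = [mk("".join(rng.choice("ACGT") for _ in range(22)), rid=f"r{i}")
                 for i in range(300)]
        k = 21
        bank = set()
        for s in (contam[0].seq, revcomp(contam[0].seq)):
            bank |= {s[i:i + k] for i in range(len(s) - k + 1)}
        expected = [r.id for r in reads
                    if not ({r.seq[i:i + k] for i in range(len(r.seq) - k + 1)} & bank)]
        got = [r.id for r in contaminant_filter(reads, contam, k)]
        assert got == expected

    def test_k_longer_than_contaminant_is_config_error(self):
        with pytest.raises(ConfigError):
            contaminant_filter([mk("ACGT" * 6)], [SeqRecord("c", "ACGTACGT")], k=21)


class TestRunQC:
    def test_identity_on_perfect_reads(self):
        reads = [mk("ACGTACGTACGTACGTAAGGTT", rid=f"r{i}") for i in range(5)]
        params = QCParams(adapter3=ADAPTER3)
        clean, rep = run_qc(reads, params)
        assert [r.seq for r in clean] == [r.seq for r in reads]
        assert len(set(rep.counts.values())) == 1

    def test_mean_phred_filter_is_strict(self):
        # mean Phred 19 after trimming -> dropped, even with low error rate
        r = mk("ACGTACGTACGT", [19] * 12)
        clean, _ = run_qc([r], QCParams())
        assert clean == []

    def test_error_rate_filter(self):
        # Phred 13 uniformly: mean error 5% > 2% -> dropped
        r = mk("ACGTACGTACGTACGTACGT", [30] * 10 + [13] * 9 + [30])
        assert expected_error_rate(r) > 0.02
        clean, _ = run_qc([r], QCParams())
        assert clean == []

    def test_short_reads_removed(self):
        r = mk("ACGTACGTA")     # 9 nt < 10
        clean, _ = run_qc([r], QCParams())
        assert clean == []

    def test_reads_with_N_discarded(self):
        r = mk("ACGTNCGTACGTACG")
        clean, _ = run_qc([r], QCParams())
        assert clean == []

    def test_funnel_monotone_and_predicates_hold(self, default_dataset, default_config):
        rep = default_dataset["report"]
        counts = [rep.counts[s] for s in rep.STAGES]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        params = default_config.qc
        k = params.contaminant_k
        bank = set()
        for c in default_dataset["contaminants"]:
            for s in (c.seq, revcomp(c.seq)):
                bank |= {s[i:i + k] for i in range(len(s) - k + 1)}
        assert all(passes_all_predicates(r, params, bank)
                   for r in default_dataset["clean"])


class TestComposition:
    def test_counts_and_fractions(self):
        reads = [mk("T" + "A" * 25), mk("T" + "G" * 25), mk("A" * 26)]
        tbl = composition_table(reads)
        row = tbl[tbl.length == 26].iloc[0]
        assert row["T"] == 2 and row["A"] == 1
        assert row["frac_T"] == pytest.approx(2 / 3)
        assert row[["frac_A", "frac_C", "frac_G", "frac_T"]].sum() == pytest.approx(1.0)

    def test_empty_input(self):
        assert composition_table([]).empty

    def test_row_sums_equal_surviving_reads(self, default_dataset):
        tbl = default_dataset["report"].composition
        in_range = [r for r in default_dataset["clean"] if 10 <= len(r) <= 39]
        assert tbl["total"].sum() == len(in_range)
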