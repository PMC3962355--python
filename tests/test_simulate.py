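"""Synthetic-data generator: determinism, planted structure, label accounting."""

import io

import numpy as np
import pytest

from coralmir.discover import _duplex_run
from coralmir.errors import ConfigError
from coralmir.fold import fold
from coralmir.formats import SeqRecord, revcomp, write_records
from coralmir.simulate import (
    SimConfig,
    make_contaminants,
    simulate_decoys,
    simulate_genome,
    simulate_ontology,
    simulate_reads,
    simulate_transcripts,
)


def fasta_bytes(records, tmp_path, name):
    p = tmp_path / name
    write_records(records, p)
    return p.read_bytes()


class TestGenome:
    def test_determinism_byte_identical(self, small_sim, tmp_path):
        g1, _ = simulate_genome(small_sim)
        g2, _ = simulate_genome(small_sim)
        assert fasta_bytes(g1, tmp_path, "a.fa") == fasta_bytes(g2, tmp_path, "b.fa")

    def test_truth_lists_every_hairpin(self, small_sim):
        _, truth = simulate_genome(small_sim)
        assert len(truth.hairpins) == small_sim.n_hairpins
        assert {h.strand for h in truth.hairpins} == {"+", "-"}

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            simulate_genome(SimConfig(n_hairpins=0))
        with pytest.raises(ConfigError):
            SimConfig(loop_len=2)
        with pytest.raises(ConfigError):
            SimConfig(five_prime_purity=1.5)

    def test_planted_windows_refold_with_designed_geometry(self, default_dataset,
                                                           default_config):
        """Folding each planted window recovers a stem with >= 60% of mature
        bases paired and the designed 3' overhang."""
        sim = default_config.sim
        contig = {c.id: c.seq for c in default_dataset["genome"]}
        for h in default_dataset["truth"].hairpins:
            local = contig[h.contig] if h.strand == "+" else revcomp(contig[h.contig])
            window = local[h.local_start : h.local_start + sim.mature_len + 70]
            fr = fold(window)
            duplex = _duplex_run(fr.pairs, 0, sim.mature_len)
            assert len(duplex) / sim.mature_len >= 0.6
            assert len(duplex) == sim.mature_len - h.overhang

    def test_planted_sequences_present_in_contigs(self, small_sim):
        genome, truth = simulate_genome(small_sim)
        contig = {c.id: c.seq for c in genome}
        for h in truth.hairpins:
            local = contig[h.contig] if h.strand == "+" else revcomp(contig[h.contig])
            assert local[h.local_start : h.local_start + len(h.mature_seq)] \
                == h.mature_seq


class TestReads:
    def test_every_read_labelled(self, small_sim):
        genome, truth = simulate_genome(small_sim)
        reads, truth = simulate_reads(genome, truth, small_sim)
        assert set(truth.read_origin) == {r.id for r in reads}

    def test_degenerate_purity_gives_single_five_prime(self):
        cfg = SimConfig(seed=3, n_hairpins=2, n_conserved=0, rescue_hairpins=0,
                        n_weak_matures=0, five_prime_purity=1.0,
                        noise_read_fraction=0.0, pirna_fraction=0.0,
                        contaminant_read_fraction=0.0,
                        reads_per_hairpin_median=50.0)
        genome, truth = simulate_genome(cfg)
        reads, truth = simulate_reads(genome, truth, cfg)
        contig = {c.id: c.seq for c in genome}
        h = truth.hairpins[0]
        local = contig[h.contig] if h.strand == "+" else revcomp(contig[h.contig])
        mature_prefix = local[h.local_start : h.local_start + 12]
        starts = {r.seq.find(mature_prefix) for r in reads
                  if truth.read_origin[r.id] == "mature"
                  and mature_prefix in r.seq}
        assert starts == {0}

    def test_pirna_fraction_has_five_prime_u_bias(self):
        cfg = SimConfig(seed=9)
        genome, truth = simulate_genome(cfg)
        reads, truth = simulate_reads(genome, truth, cfg)
        pirna = [r for r in reads if truth.read_origin[r.id] == "pirna"]
        assert len(pirna) > 500
        frac_t = np.mean([r.seq[0] == "T" for r in pirna])
        assert frac_t == pytest.approx(0.9, abs=0.04)

    def test_determinism(self, small_sim, tmp_path):
        g, t = simulate_genome(small_sim)
        r1, _ = simulate_reads(g, t, small_sim)
        r2, _ = simulate_reads(g, t, small_sim)
        assert [(a.id, a.seq, a.quals) for a in r1] == \
               [(a.id, a.seq, a.quals) for a in r2]


class TestTranscripts:
    def test_sites_planted_and_verified(self, small_sim):
        genome, truth = simulate_genome(small_sim)
        matures = [SeqRecord(h.mature_id, h.mature_seq) for h in truth.hairpins]
        tx, site_truth = simulate_transcripts(matures, small_sim)
        assert len(tx) == small_sim.n_transcripts
        strong = [s for s in site_truth.sites if s.klass == "strong"]
        weak = [s for s in site_truth.sites if s.klass == "weak"]
        assert len(strong) == small_sim.n_strong_sites
        assert len(weak) == small_sim.n_weak_sites
        assert all(s.designed_ddg <= small_sim.planted_site_ddG_strong
                   for s in strong)
        assert all(s.designed_ddg >= small_sim.planted_site_ddG_weak
                   for s in weak)

    def test_mature_shorter_than_seed_rejected(self, small_sim):
        with pytest.raises(ConfigError):
            simulate_transcripts([SeqRecord("m", "ACGTACG")], small_sim)


class TestOntology:
    def test_determinism_and_structure(self, small_sim):
        d1, a1, s1, t1 = simulate_ontology(small_sim)
        d2, a2, s2, t2 = simulate_ontology(small_sim)
        assert a1 == a2 and t1 == t2 and s1 == s2
        assert t1 in d1.terms
        assert len(d1) == small_sim.n_go_terms

    def test_effect_must_exceed_one(self, small_sim):
        from dataclasses import replace
        with pytest.raises(ConfigError):
            simulate_ontology(replace(small_sim, enriched_term_effect=1.0))


class TestDecoys:
    def test_decoys_have_planted_like_stacks(self, small_sim):
        decoys = simulate_decoys(small_sim, 20)
        assert len(decoys) == 20
        for cand, reads in decoys:
            assert len(cand.seq) == small_sim.mature_len + 70
            assert len(reads) >= 30


def test_contaminants_total_about_two_kilobases(small_sim):
    total = sum(len(c.seq) for c in make_contaminants(small_sim))
    assert 1500 <= total <= 2500
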