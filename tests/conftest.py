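import pytest

from coralmir.pipeline import PipelineConfig
from coralmir.qc import run_qc
from coralmir.simulate import (
    SimConfig,
    make_contaminants,
    make_known_reference,
    simulate_genome,
    simulate_reads,
)


@pytest.fixture(scope="session")
def default_config():
    """The study conditions the acceptance checks run under."""
    return PipelineConfig(seed=42)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """Default synthetic library, generated once per session."""
    sim = default_config.sim
    genome, truth = simulate_genome(sim)
    reads, truth = simulate_reads(genome, truth, sim)
    known = make_known_reference(truth, sim)
    contaminants = make_contaminants(sim)
    clean, report = run_qc(reads, default_config.qc, contaminants)
    return {
        "genome": genome, "truth": truth, "reads": reads, "known": known,
        "contaminants": contaminants, "clean": clean, "report": report,
    }


@pytest.fixture(scope="session")
def small_sim():
    """A fast, reduced configuration for unit-level pipeline checks."""
    return SimConfig(
        seed=7, n_hairpins=4, n_conserved=1, n_weak_matures=2,
        rescue_hairpins=1, reads_per_hairpin_median=80.0,
        n_transcripts=10, n_strong_sites=3, n_weak_sites=3,
        n_go_terms=12, n_background_genes=150, study_size=20,
    )
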