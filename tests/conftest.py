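import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from circscreen import (
    annotate_exon_boundaries,
    call_backsplice_junctions,
    design_panel,
    make_toy_annotation,
    simulate_backsplice_reads,
)
from circscreen.simulate import SimConfig


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=11, channel_noise=0.0)


@pytest.fixture(scope="session")
def toy_annotation(sim_config):
    return make_toy_annotation(sim_config)


@pytest.fixture(scope="session")
def toy_junctions(toy_annotation, sim_config):
    """Junctions re-discovered from simulated chimeric reads, annotated."""
    genome, transcripts, planted = toy_annotation
    records, _, truth = simulate_backsplice_reads(
        transcripts, planted, None, sim_config
    )
    called = call_backsplice_junctions(records, genome)
    return annotate_exon_boundaries(called, transcripts)


@pytest.fixture(scope="session")
def toy_panel(toy_annotation, toy_junctions):
    genome, transcripts, _ = toy_annotation
    targets, probes, codebook = design_panel(
        toy_junctions, transcripts, genome, barcode_seed=7
    )
    return targets, probes, codebook
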