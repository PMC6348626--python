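"""Shared fixtures: one default synthetic dataset reused across the suite."""

import pytest

from lncovule import synthio


@pytest.fixture(scope="session")
def default_data():
    """Default benchmark dataset (genome, annotation, transcripts, truth)."""
    return synthio.simulate_genome(synthio.SimulationConfig.default(seed=7))


@pytest.fixture(scope="session")
def default_counts(default_data):
    counts, design = synthio.simulate_counts(default_data)
    return counts, design


@pytest.fixture(scope="session")
def grouped_fpkm(default_data, default_counts):
    from lncovule import quantexpr

    counts, design = default_counts
    lengths = {tid: t.length for tid, t in default_data.transcripts.items()}
    fpkm = quantexpr.fpkm_matrix(counts, lengths)
    return quantexpr.integrate_replicates(fpkm, design["group"])
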