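import pytest

import drnamap as d


@pytest.fixture(scope="session")
def small_sim():
    """A compact synthetic organism shared across tests (fast to generate)."""
    cfg = d.SimConfig(genome_length=300_000, n_units=40, srna_count=5, seed=7)
    return d.simulate(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """The default study conditions: 2-Mb genome, 250 units, seed 42."""
    return d.simulate(d.SimConfig())


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    res = default_sim
    return d.run_all(res.minus, res.plus, res.coverage, res.features,
                     genome_seq=res.sequence)


def make_point(position, strand, minus, plus, M, A):
    return d.MAPoint(position, strand, minus, plus, M, A)


def make_enriched(position, strand="+", plus=50, M=6.0, A=5.0, enriched=True):
    point = d.MAPoint(position, strand, 3, plus, M, A)
    return d.EnrichedSite(point, enriched)
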