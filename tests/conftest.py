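import pytest

from lilrseq import read_processing as rp
from lilrseq.synthetic import (
    SimConfig,
    canonical_fixture,
    simulate_allele_set,
    simulate_ccs_reads,
)


@pytest.fixture(scope="session")
def lilrb1():
    return canonical_fixture("LILRB1")


@pytest.fixture(scope="session")
def lilrb2():
    return canonical_fixture("LILRB2")


@pytest.fixture(scope="session")
def small_sim():
    """Desk-scale noise-free study: 3 lineages x 4 alleles, 6 samples."""
    cfg = SimConfig(seed=5, n_samples=6, reads_per_sample=60, ccs_error_rate=0.0)
    truth = simulate_allele_set(cfg)
    reads, truth = simulate_ccs_reads(truth, cfg)
    return cfg, truth, reads


@pytest.fixture(scope="session")
def small_demuxed(small_sim):
    cfg, truth, reads = small_sim
    ccs = [rp.CcsRead(i, s, q) for i, s, q in reads]
    kept = rp.filter_by_quality(ccs, 0.99)
    per_sample, unassigned = rp.demultiplex(kept, truth.barcodes, 1)
    return cfg, truth, per_sample, unassigned
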