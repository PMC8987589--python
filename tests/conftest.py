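import pytest

from cfdyn import (
    SimConfig, default_planted_genes, simulate_cohort,
    synthetic_signature_matrix,
)


@pytest.fixture(scope="session")
def sigs5():
    """Small synthetic 5-signature reference matrix."""
    return synthetic_signature_matrix(n_signatures=5, seed=7)


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """One default simulated cohort (20 patients, planted drivers), shared
    read-only across tests."""
    d = tmp_path_factory.mktemp("cohort")
    cfg = SimConfig(planted_resistance=default_planted_genes(), seed=11)
    manifest, truth = simulate_cohort(cfg, d)
    return d, cfg, manifest, truth
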