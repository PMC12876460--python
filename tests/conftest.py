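import pytest

from vertescreen.synthetic import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully structured simulation shared across test modules."""
    cfg = SimConfig(
        seed=11,
        n_genes=500,
        n_target_genes=60,
        n_planted_spatial_clusters=4,
        genes_per_cluster=5,
        cluster_span_bp=100_000,
        n_animals_per_stratum=50,
    )
    return cfg, simulate_all(cfg)
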