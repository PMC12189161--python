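import numpy as np
import pytest

from ripsplice.simulate import default_config, simulate_gene_models, simulate_junction_counts


@pytest.fixture(scope="session")
def fixture_models():
    """Default-fixture gene models plus per-gene event ground truth."""
    cfg = default_config(123)
    models, truth = simulate_gene_models(cfg, np.random.default_rng(cfg.seed))
    return cfg, models, truth


@pytest.fixture(scope="session")
def fixture_junctions(fixture_models):
    cfg, models, truth = fixture_models
    table = simulate_junction_counts(cfg, models, truth, np.random.default_rng(cfg.seed + 2))
    return cfg, models, truth, table


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
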