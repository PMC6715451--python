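import pytest

from irlnet.synthetic_data import (
    SyntheticConfig,
    generate_expression_dataset,
    generate_interaction_tables,
    planted_truth,
)


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """Desk-scale study: same structure as the default, fewer background
    features so the permutation stages stay fast."""
    return SyntheticConfig(n_lncrna=60, n_mrna=300, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return planted_truth(small_cfg)


@pytest.fixture(scope="session")
def small_tables(small_cfg):
    lnc, mrna, truth = generate_interaction_tables(small_cfg)
    return lnc, mrna, truth


@pytest.fixture(scope="session")
def small_bundle(small_cfg, small_truth):
    return generate_expression_dataset(small_cfg, small_truth)
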