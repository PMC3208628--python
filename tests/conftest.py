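import numpy as np
import pytest

from tfcohort import expression, motif, synthetic


@pytest.fixture(scope="session")
def small_config():
    return synthetic.SyntheticConfig(
        n_genes=300, n_targets=30, n_comparisons=3, n_groups=20,
        group_size=20, n_enriched_groups=5, seed=1, n_decoys=2,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return synthetic.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_scores(small_dataset):
    return expression.build_score_table(
        small_dataset.comparisons, small_dataset.truth.regulator_gene
    )


@pytest.fixture(scope="session")
def small_tp(small_dataset):
    return motif.build_propensity_table(
        small_dataset.promoters, small_dataset.regulator_pwm
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
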