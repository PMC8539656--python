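"""Shared fixtures: small seeded synthetic worlds, generated at test time."""

import pytest

from gerochem import SyntheticConfig, gen_world

#: conditions of the planted-recovery study: enough cells per pair to
#: memorize pair membership, a GO vocabulary dense enough that gene
#: profiles are distinct, planted-up pairs filling the 5% percentile
#: quota, and an effect size that clears the background tail.
RECOVERY_CONFIG = dict(
    n_genes=200, n_drugs=30, n_cells=10, n_go_terms=400,
    planted_pairs=40, effect_size=6.0, n_background_pairs=360,
)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=11, n_drugs=12, n_genes=60, n_cells=5,
                           n_go_terms=40, n_mutation_markers=8, n_cpg_sites=30,
                           planted_pairs=6, n_background_pairs=80)


@pytest.fixture(scope="session")
def small_world(small_config):
    return gen_world(small_config)
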