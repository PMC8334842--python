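import dataclasses

import pytest

from phylometa.bpmm import MCMCSettings
from phylometa.effect_sizes import build_species_table
from phylometa.phylo import phylo_correlation
from phylometa.simulate import GeneratorParams, generate

#: short single-chain settings for replicate batteries and smoke runs
REPLICATE_SETTINGS = MCMCSettings(iterations=6000, burn_in=1000, thin=5, n_chains=1)


def replicate_settings(seed: int, **kw) -> MCMCSettings:
    return dataclasses.replace(REPLICATE_SETTINGS, seed=seed, **kw)


@pytest.fixture(scope="session")
def synthetic_dataset():
    """One default 41-species synthetic dataset: (raw, table, cov, truth)."""
    raw, tree, truth = generate(GeneratorParams(seed=20210811))
    table = build_species_table(raw)
    cov = phylo_correlation(tree)
    return raw, table, cov, truth
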