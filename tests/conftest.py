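import numpy as np
import pytest

from mitocomp import SimulationConfig, make_reference_cds, simulate


@pytest.fixture(scope="session")
def small_bundle():
    """A 4-species simulation at moderate divergence, shared across tests."""
    cfg = SimulationConfig(seed=11, n_species=4, per_branch_sub_rate=0.02)
    genomes, truth = simulate(cfg)
    refs = dict(make_reference_cds(cfg))
    return cfg, genomes, truth, refs


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_dna(rng, n, p=(0.25, 0.25, 0.25, 0.25)):
    return "".join(rng.choice(list("ACGT"), size=n, p=list(p)))
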