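import pytest

import promotercpg as pc


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic dataset (both strands, labels, truth)."""
    cfg = pc.SyntheticGenomeConfig(n_genes=60, scaffold_len=60_000, seed=11)
    return pc.simulate_dataset(cfg)
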