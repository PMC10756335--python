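import numpy as np
import pytest

from cdrlearn.synthetic import SyntheticSpec, generate_dataset, load_smiles_library


@pytest.fixture(scope="session")
def smiles_library() -> list[str]:
    return list(load_smiles_library()["smiles"])


@pytest.fixture(scope="session")
def small_synthetic():
    """A small planted-signal dataset shared by model-level tests."""
    spec = SyntheticSpec(m=24, n_drugs=12, d_genes=60, seed=11)
    syn = generate_dataset(spec)
    return syn, syn.to_dataset()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
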