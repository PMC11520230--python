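import numpy as np
import pytest

from dice.data_io import GeneSetCollection, ModalityMatrix, PairedDataset
from dice.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_result():
    """Small, quick paired dataset with 4 planted clusters."""
    return generate(SyntheticConfig(n=120, n_clusters=4, latent_dim=8,
                                    dim_v=16, dim_x=16, noise_sd=0.2, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_pair():
    """Minimal 6-protein paired dataset for structural tests."""
    ids = [f"P{i}" for i in range(6)]
    r = np.random.default_rng(0)
    mv = ModalityMatrix(ids, r.normal(size=(6, 4)), "v")
    mx = ModalityMatrix(ids, r.normal(size=(6, 3)), "x")
    return PairedDataset(ids, mv, mx)


@pytest.fixture()
def simple_sets():
    return GeneSetCollection({"S1": {"A", "B"}, "S2": {"C", "D", "E"}})
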