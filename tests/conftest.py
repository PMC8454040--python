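import numpy as np
import pytest

from latentpath import ToyChemistry, make_toy_universe, simulate


@pytest.fixture(scope="session")
def identity_toy() -> ToyChemistry:
    """2-fragment chemistry with identity mixing: latents equal fragment counts."""
    universe = {
        "C0": np.array([1, 0]),
        "C1": np.array([0, 1]),
        "C2": np.array([1, 1]),
        "C3": np.array([2, 1]),
        "C4": np.array([2, 2]),
        "C5": np.array([0, 2]),
    }
    return ToyChemistry(
        fragment_masses=[10.0, 14.0], mixing_matrix=np.eye(2), universe=universe
    )


@pytest.fixture(scope="session")
def toy_universe() -> ToyChemistry:
    return make_toy_universe(n_compounds=50, n_fragments=6, latent_dim=8, seed=1)


@pytest.fixture(scope="session")
def small_world():
    """Small simulated world shared by design/scoring/evaluation tests."""
    return simulate(n_compounds=100, n_reactions=180, n_ec_classes=6, seed=11)
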