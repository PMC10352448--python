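import numpy as np
import pytest

from metapopne import make_island, solve_equilibrium, local_weights


@pytest.fixture(scope="session")
def fig1_model():
    """Island model with s=10 demes of census and effective size 50 and
    migration parameter m=0.1 — the reference model for the equilibrium
    and design analyses."""
    return make_island(10, 0.1, 50, 50)


@pytest.fixture(scope="session")
def fig1_state(fig1_model):
    return solve_equilibrium(fig1_model)


@pytest.fixture(scope="session")
def e1():
    return local_weights(10, 0)


def random_irreducible_model(rng, s=None, max_s=5):
    """A random strictly-positive (hence irreducible) migration matrix with
    random local sizes, for property tests."""
    from metapopne import PopulationModel

    s = s or rng.integers(2, max_s + 1)
    B = rng.uniform(0.05, 1.0, size=(s, s))
    B /= B.sum(axis=1, keepdims=True)
    Nc = rng.integers(5, 200, size=s).astype(float)
    Ne = np.maximum(1.0, np.floor(Nc * rng.uniform(0.3, 1.0, size=s)))
    return PopulationModel(B=B, Nc=Nc, Ne=Ne)
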