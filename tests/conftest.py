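import numpy as np
import pandas as pd
import pytest

from mosscoda import GeneratorConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def default_survey():
    """One default synthetic survey (30 samples x 29 elements) with truth."""
    return generate(seed=1)


@pytest.fixture(scope="session")
def small_survey():
    """A compact survey (8 elements, 10+10 samples) for fast pipeline tests."""
    config = GeneratorConfig(
        n_per_group=10,
        elements=("Al", "Fe", "Sc", "Mn", "Pb", "Cd", "Na", "K"),
        crustal_set=("Al", "Fe", "Sc"),
        anthropogenic_set=("Pb", "Cd"),
        antagonist="Mn",
        antagonist_partners=("Pb", "Cd"),
        shifted_up=("Pb", "Cd"),
        seed=11,
    )
    return generate(config)


def random_composition(rng, d=5, k=1.0):
    return k * (lambda p: p / p.sum())(rng.gamma(2.0, size=d))


@pytest.fixture
def random_closed_matrix(rng):
    vals = rng.lognormal(0.0, 0.5, size=(12, 6))
    vals = vals / vals.sum(axis=1, keepdims=True)
    return pd.DataFrame(vals, columns=list("abcdef"))
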