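import pytest

from ecdyn.toys import (DualSubstrateToySpec, OverflowToySpec,
                        dual_substrate_toy, overflow_toy)


@pytest.fixture
def toy():
    """Default overflow toy: (model, analytic oracle)."""
    return overflow_toy()


@pytest.fixture
def toy_model(toy):
    return toy[0]


@pytest.fixture
def toy_analytic(toy):
    return toy[1]


@pytest.fixture
def toy_assim():
    """Overflow toy with the ethanol re-assimilation route."""
    return overflow_toy(OverflowToySpec(include_ethanol_assimilation=True))


@pytest.fixture
def dual_toy():
    return dual_substrate_toy(DualSubstrateToySpec())


def random_overflow_spec(rng):
    """Draw a valid overflow parameterisation (overflow regime enforced:
    fermentation cheaper per unit growth, respiration higher-yield)."""
    y_r = rng.uniform(0.06, 0.14)
    # fermentative biomass carbon + ethanol must fit in the substrate carbon
    y_f = min(rng.uniform(0.3, 0.8) * y_r, 0.099)
    c_r = rng.uniform(0.005, 0.02)
    # ensure c_f < c_r and c_f/y_f < c_r/y_r with margin
    c_f = rng.uniform(0.1, 0.8) * c_r * y_f / y_r
    pool = rng.uniform(0.01, 0.04)
    q_max = rng.uniform(5.0, 15.0)
    return OverflowToySpec(y_r=y_r, y_f=y_f, c_r=c_r, c_f=c_f,
                           pool=pool, q_max=q_max)
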