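import numpy as np
import pytest

from agestruct.life_tables import AgeFecundityModel, LifeTable, build_theoretical_life_table
from agestruct.synthetic_data import table1_fixture


@pytest.fixture(scope="session")
def traits():
    return table1_fixture()


@pytest.fixture(scope="session")
def semelparous_table():
    """One age class, reproduce then die: the Wright-Fisher limit."""
    return LifeTable(
        ages=np.array([1]), survival=np.array([0.0]),
        rel_fecundity=np.array([1.0]), maturity=1.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def random_life_table(rng, max_omega=12):
    """Random valid life table spanning type I-III survivorship shapes."""
    omega = int(rng.integers(2, max_omega + 1))
    c = float(10 ** rng.uniform(np.log10(0.01), np.log10(30)))
    maturity = float(rng.integers(1, max(2, omega // 2 + 1)))
    model = rng.choice(["constant", "exponential"])
    f = float(rng.uniform(-0.5, 0.5)) if model == "exponential" else 0.0
    return build_theoretical_life_table(maturity, omega, c, AgeFecundityModel(model, f=f))
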