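import pytest

from coronene_fractals import FractalSpec, benzenoid_from_cells, coronene_unit


@pytest.fixture(scope="session")
def benzene():
    return benzenoid_from_cells([(0, 0)], family_tag="benzene")


@pytest.fixture(scope="session")
def naphthalene():
    return benzenoid_from_cells([(0, 0), (2, 0)], family_tag="naphthalene")


@pytest.fixture(scope="session")
def anthracene():
    return benzenoid_from_cells([(0, 0), (2, 0), (4, 0)], family_tag="anthracene")


@pytest.fixture(scope="session")
def pyrene():
    return benzenoid_from_cells(
        [(0, 0), (2, 0), (1, 3), (1, -3)], family_tag="pyrene"
    )


@pytest.fixture(scope="session")
def coronene():
    return coronene_unit().graph()


def all_small_specs(max_n: int = 3):
    """Every family spec with n, m up to max_n."""
    specs = [FractalSpec("ZHCF", n) for n in range(1, max_n + 1)]
    specs += [FractalSpec("AHCF", n) for n in range(1, max_n + 1)]
    specs += [
        FractalSpec("RCF", n, m)
        for m in range(1, max_n + 1)
        for n in range(1, max_n + 1)
    ]
    return specs
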