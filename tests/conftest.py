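import pytest

from sigscreen import load_nrf2_biomarker
from sigscreen.running_fisher import RfParams
from sigscreen.synthetic import gene_universe, make_biomarker


@pytest.fixture(scope="session")
def nrf2():
    """Packaged synthetic Nrf2-style biomarker (75 probes / 48 genes)."""
    return load_nrf2_biomarker()


@pytest.fixture(scope="session")
def universe20k(nrf2):
    return gene_universe(20000, include=sorted(nrf2.genes))


@pytest.fixture(scope="session")
def rf20k():
    return RfParams(universe_size=20000)


@pytest.fixture(scope="session")
def small_biomarker():
    """A 30-gene synthetic biomarker for fast screening tests."""
    return make_biomarker("bmA", n_up=20, n_down=10, seed=11)
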