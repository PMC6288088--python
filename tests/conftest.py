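import numpy as np
import pytest

from coocnet.io_tables import TaxaCountTable


@pytest.fixture
def toy_table() -> TaxaCountTable:
    """3 taxa x 2 samples with unequal depths."""
    return TaxaCountTable(
        ["taxA", "taxB", "taxC"],
        ["s1", "s2"],
        np.array([[10, 30], [90, 70], [0, 100]]),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
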