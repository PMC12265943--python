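import numpy as np
import pytest

from mirabs.synthetic_data import (
    generate_hairpin_reference,
    generate_spikein_pool,
)


@pytest.fixture(scope="session")
def reference():
    """Twenty random hairpins with mature annotations (session-wide, seeded)."""
    return generate_hairpin_reference(20, seed=11)


@pytest.fixture(scope="session")
def small_reference():
    """Five hairpins, small enough for exhaustive-oracle comparisons."""
    return generate_hairpin_reference(5, seed=23)


@pytest.fixture(scope="session")
def pool(reference):
    """Nine equimolar spike-in oligos avoiding the reference."""
    return generate_spikein_pool(9, 9e-18, seed=7, reference=reference)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
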