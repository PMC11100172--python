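import numpy as np
import pytest

from redflesh import generate_panel, generate_scan


@pytest.fixture(scope="session")
def small_scan():
    """Four-disk synthetic scan with moderate heterogeneity, known truth."""
    return generate_scan(4, heterogeneity=0.3, radius_px=80, margin=25, seed=7)


@pytest.fixture(scope="session")
def panel():
    """Default 91-genotype synthetic panel (profiles, descriptors, truth)."""
    return generate_panel(91, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
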