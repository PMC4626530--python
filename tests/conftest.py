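import numpy as np
import pytest

from meafield import SliceGeometry, default_geometry


@pytest.fixture
def geo() -> SliceGeometry:
    """Reference slice: h = 300 um, sigma_T = 0.3, sigma_S = 1.5 S/m."""
    return default_geometry()


@pytest.fixture
def semi_infinite() -> SliceGeometry:
    """No conductivity jump at the bath interface (W_TS = 0)."""
    return SliceGeometry(h=300e-6, sigma_T=0.3, sigma_S=0.3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
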