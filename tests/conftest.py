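import numpy as np
import pytest

from reefadapt import synthetic


@pytest.fixture(scope="session")
def small_grid():
    """A 15-cell connected reef grid on a 6x5 raster (5 km pixels)."""
    return synthetic.gen_reef_grid(6, 5, 0.5, 25.0, seed=1)


@pytest.fixture(scope="session")
def site_baf_gradient():
    """Eight sampling sites spanning BAF 0 to 0.3."""
    return {f"s{i}": b for i, b in enumerate(np.linspace(0.0, 0.3, 8))}
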