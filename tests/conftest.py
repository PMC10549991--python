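import numpy as np
import pytest

from scaffsim import (
    LoadProtocol,
    ScaffoldSpec,
    build_scaffold_surface,
)


@pytest.fixture(scope="session")
def reference_spec():
    """Reference scaffold dimensions (R=0.35, Y=1.4, h=1.12, D=10, H=4.8 mm)."""
    return ScaffoldSpec()


@pytest.fixture(scope="session")
def coarse_mesh(reference_spec):
    """Coarse but full-lattice surface mesh (fast; ~6.5k nodes)."""
    return build_scaffold_surface(reference_spec, resolution=8)


@pytest.fixture
def protocol_10pct():
    return LoadProtocol(frequency=1.0, amplitude_fraction=0.10, scaffold_height=4.8)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
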