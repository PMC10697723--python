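import numpy as np
import pytest

from vesselflux import SimulationConfig


@pytest.fixture
def cfg():
    """Default study-condition configuration, fixed seed."""
    return SimulationConfig(seed=42)


@pytest.fixture
def short_diffusion_cfg():
    """Diffusion config truncated to 60 s; the fit window uses early frames
    only, so a shorter movie measures the same thing faster."""
    return SimulationConfig(seed=42, duration=60.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
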