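"""Shared fixtures: phantoms are generated once per session."""

import numpy as np
import pytest

from shouldersim import PhantomSpec, make_shoulder_phantom


@pytest.fixture(scope="session")
def noiseless_spec():
    """Three-level piecewise-constant phantom: air, soft tissue, cortical bone."""
    return PhantomSpec(noise_sd=0.0, trabecular_amplitude=0.0, air_level=0.0)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    return make_shoulder_phantom(noiseless_spec, seed=1)


@pytest.fixture(scope="session")
def textured_phantom():
    """Default phantom: trabecular texture and mild background noise."""
    return make_shoulder_phantom(PhantomSpec(), seed=3)
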