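import numpy as np
import pytest

from brswedge.cell import ChannelScales, PacingProtocol, steady_trace


@pytest.fixture(scope="session")
def epi_trace():
    """Steady-state baseline epicardial AP at CL 800 ms (0.25 ms samples)."""
    return steady_trace(True, ChannelScales(), PacingProtocol())


@pytest.fixture(scope="session")
def endo_trace():
    return steady_trace(False, ChannelScales(), PacingProtocol())


@pytest.fixture(scope="session")
def tiny_geometry():
    """Small 2D sheet for fast tissue-level unit tests."""
    from brswedge.scenarios import GeometryConfig
    return GeometryConfig(dims=(16.0, 6.0), target_edge=0.8, seed=3)
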