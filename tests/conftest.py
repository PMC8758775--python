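import numpy as np
import pytest

from choroidchip import ImageStack


@pytest.fixture
def cubic_stack():
    """Factory for small cubic-voxel stacks."""

    def _make(voxels, edge_um=1.0, channel=""):
        return ImageStack(
            voxels=np.asarray(voxels, dtype=np.float64),
            spacing_xyz=(edge_um, edge_um, edge_um),
            channel=channel,
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
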