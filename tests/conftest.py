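import numpy as np
import pytest

import spikeseg as ss


@pytest.fixture(scope="session")
def tiny_arch():
    """A small 3-layer architecture (<2k params) for fast structural tests."""
    return ss.ArchitectureSpec(
        n_filters=4, n_classes=3, variant="ssd",
        layer_table=(ss.LayerSpec(3, 1), ss.LayerSpec(3, 2),
                     ss.LayerSpec(1, 1, relu=False)),
    )


@pytest.fixture(scope="session")
def phantom_pair():
    spec = ss.PhantomSpec(side_length=64, n_classes=8, seed=1)
    return ss.generate_phantom(spec)


@pytest.fixture(scope="session")
def small_phantom_pair():
    spec = ss.PhantomSpec(side_length=32, n_classes=5, seed=3)
    return ss.generate_phantom(spec)
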