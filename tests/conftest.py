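import numpy as np
import pytest

from histadapt import (PhantomObject, PhantomScene, Volume, build_network,
                       render_phantom, tiny_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    return Volume(data=rng.normal(size=(16, 16, 16)).astype(np.float32),
                  spacing=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def structure_phantom():
    """A small structures-mode phantom with one ellipsoid per class."""
    scene = PhantomScene(
        shape=(24, 24, 24),
        mode="structures",
        objects=(
            PhantomObject(1, (7.0, 12.0, 12.0), (3.0, 3.0, 3.0), 0.6),
            PhantomObject(2, (16.0, 12.0, 12.0), (3.0, 3.0, 3.0), 0.8),
        ),
        seed=42,
    )
    return render_phantom(scene)


@pytest.fixture(scope="session")
def lesion_phantom():
    scene = PhantomScene(
        shape=(24, 24, 24),
        mode="lesions",
        objects=(
            PhantomObject(1, (10.0, 10.0, 12.0), (2.0, 2.0, 2.0), 0.9),
            PhantomObject(1, (15.0, 14.0, 12.0), (1.5, 1.5, 1.5), 0.9),
        ),
        seed=43,
    )
    return render_phantom(scene)


@pytest.fixture(scope="session")
def tiny_network():
    """An untrained tiny network for forward-pass contracts (4 classes, K=4)."""
    return build_network(tiny_spec(prior_units=4, out_classes=4, patch_size=9), seed=7)
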