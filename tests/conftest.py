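import numpy as np
import pytest

from ctvbm.head_phantom import PhantomSpec, make_atlas, make_labels
from ctvbm.volume_io import GridSpec, Volume3D


@pytest.fixture(scope="session")
def spec():
    """The default 48^3 / 4 mm phantom specification."""
    return PhantomSpec()


@pytest.fixture(scope="session")
def atlas(spec):
    """Tissue-prior atlas built once from the template phantom."""
    return make_atlas(spec)


@pytest.fixture(scope="session")
def template_labels(spec):
    return make_labels(spec, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return GridSpec.isotropic((16, 16, 16), 2.0)


@pytest.fixture
def random_volume(small_grid, rng):
    return Volume3D(rng.normal(size=small_grid.shape), small_grid.affine, "mr")
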