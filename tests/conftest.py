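import numpy as np
import pytest

from fluorograde.phantom import PhantomParams, generate_core

#: Desk-scale phantom geometry: 512 px at 0.96 um/px, so one 245.52 um crop
#: spans 256 px and four crops tile a core.
DESK_PARAMS = dict(canvas_px=(512, 512), pixel_pitch_um=0.96)


@pytest.fixture(scope="session")
def desk_core():
    """One deterministic desk-scale phantom core (DE, labels, epi, HE)."""
    return generate_core(PhantomParams(**DESK_PARAMS, rng_seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
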