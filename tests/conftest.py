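import numpy as np
import pytest
from hypothesis import settings

import retvol as rv
from retvol import phantom as ph

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def geometry() -> rv.ScanGeometry:
    return rv.ScanGeometry()


@pytest.fixture(scope="session")
def default_phantom(geometry):
    """Default centred-pit phantom volume with its ground truth."""
    return ph.synthesize_label_volume(geometry, ph.PhantomParams())


@pytest.fixture(scope="session")
def flat_phantom(geometry):
    """Pit-free phantom with constant 260 µm retinal thickness."""
    return ph.synthesize_label_volume(geometry, ph.PhantomParams.flat(260.0))


@pytest.fixture(scope="session")
def offset_phantom(geometry):
    params = ph.PhantomParams(pit_center_offset_mm=(0.4, 0.221))
    return ph.synthesize_label_volume(geometry, params)


@pytest.fixture(scope="session")
def default_cohort():
    """Simulated 374-eye cohort at the calibrated defaults."""
    return ph.simulate_cohort(ph.EffectDesign(seed=11))


def subseed(base: int, index: int) -> int:
    """Deterministic child seed below 2**31."""
    child = np.random.SeedSequence(base).spawn(index + 1)[index]
    return int(child.generate_state(1)[0] % (2**31))
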