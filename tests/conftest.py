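import numpy as np
import pytest

from omvar.models import LabelMap
from omvar.simulate import NoiseModel, simulate_reference


@pytest.fixture(scope="session")
def small_ref():
    """One 5-Mb chromosome, ~10-kb label spacing."""
    return simulate_reference(1, 5_000_000, 10_000, seed=11)


@pytest.fixture(scope="session")
def default_noise():
    return NoiseModel()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def submap(ref_map, start, end, map_id="mol"):
    """Noiseless molecule copied from a reference window."""
    sel = ref_map.positions[(ref_map.positions >= start) & (ref_map.positions < end)]
    return LabelMap(map_id, "molecule", float(end - start), sel - start)
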