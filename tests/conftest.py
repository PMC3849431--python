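import numpy as np
import pytest

from fishq import MISPProfile
from fishq.pipeline import quantify_core
from fishq.simulate import SimParams, simulate_core


@pytest.fixture(scope="session")
def default_profile() -> MISPProfile:
    return MISPProfile()


@pytest.fixture(scope="session")
def sim_core():
    """One default synthetic core (40 nuclei, half amplified, 5 planes)."""
    params = SimParams(seed=11)
    stacks, truth = simulate_core(params, core_id="fixture-core")
    return params, stacks, truth


@pytest.fixture(scope="session")
def quantified_core(sim_core, default_profile):
    """The fixture core pushed through the full pipeline once."""
    _, stacks, truth = sim_core
    result = quantify_core(stacks, default_profile, core_id="fixture-core")
    return result, truth


def disk_image(shape, center, radius, fg=200, bg=10, dtype=np.uint8):
    """A hard-edged disk on flat background."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img = np.full(shape, bg, dtype=dtype)
    img[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2] = fg
    return img
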