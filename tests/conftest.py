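import numpy as np
import pytest
from hypothesis import settings

import rd5d

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def mini_scheme():
    return rd5d.preset_scheme("mini")


@pytest.fixture(scope="session")
def full45_scheme():
    return rd5d.preset_scheme("full45")


@pytest.fixture
def wm_component():
    return rd5d.preset_component("wm", rng=0)


@pytest.fixture
def csf_component():
    return rd5d.preset_component("csf")


def random_component(rng, margin=0.15, weight=1.0):
    """A component drawn uniformly inside the default sampling box,
    keeping a margin from the box edges."""
    box = rd5d.SamplingBox()
    return rd5d.Component(
        r2=10 ** rng.uniform(box.log10_r2[0] + margin,
                             box.log10_r2[1] - margin),
        d_par=10 ** rng.uniform(box.log10_d_par[0] + margin,
                                box.log10_d_par[1] - margin),
        d_perp=10 ** rng.uniform(box.log10_d_perp[0] + margin,
                                 box.log10_d_perp[1] - margin),
        theta=float(np.arccos(rng.uniform(0.1, 0.9))),
        phi=float(rng.uniform(0.1, 2 * np.pi - 0.1)),
        weight=weight,
    )
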