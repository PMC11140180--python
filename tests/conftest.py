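import numpy as np
import pytest

from placentamri.model import PlacentomeModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def typical_params():
    """Placental parameters typical of a healthy late-gestation placentome."""
    return PlacentomeModelParams(
        f=0.25, d=1.5e-3, d_star=0.03, t2fb=60.0, v=0.25, s0=100.0
    )


def draw_feasible_params(rng, s0_range=(0.5, 200.0)):
    """Random parameters satisfying every box and the f+v<1 constraint."""
    f = rng.uniform(0.02, 0.9)
    v = rng.uniform(0.02, min(0.9, 0.96 - f))
    return PlacentomeModelParams(
        f=f,
        d=rng.uniform(1e-4, 5e-3),
        d_star=rng.uniform(5e-3, 0.2),
        t2fb=rng.uniform(20.0, 140.0),
        v=v,
        s0=rng.uniform(*s0_range),
    )
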