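import numpy as np
import pytest

from signoise import ModelSpec, Reaction, ReactionSystem
from signoise.defaults import VOLUME_RECEPTOR_L


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def binding_system():
    """Receptor-signal binding at K_eq = 100 counts (1e-7 M), N_RT=10, N_S=100."""
    from signoise import build_model

    spec = ModelSpec.binding(keq_m=1e-7)
    return build_model(spec, 100)


@pytest.fixture
def constant_rate_system():
    """Two channels with constant propensities 3.0 and 1.0 s^-1.

    The first channel increments a counter species that no propensity reads,
    so the fired channel is identifiable from the state change.
    """
    return ReactionSystem(
        species=("A", "B", "hits"),
        reactions=(
            Reaction("first-order-synthesis", 1.0, ("A",), {"hits": +1}, name="a"),
            Reaction("first-order-synthesis", 1.0, ("B",), {}, name="b"),
        ),
        volume_liters=VOLUME_RECEPTOR_L,
    )
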