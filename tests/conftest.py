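import pytest
from hypothesis import settings

import bsrkit as b

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return b.load_registry()


@pytest.fixture(scope="session")
def packed_bed():
    """1 L up-flow packed bed sampled at thirds of the cumulative volume."""
    return b.ReactorGeometry("upbr", "plug_flow", 1.0, (0.33, 0.66, 1.0))


@pytest.fixture(scope="session")
def stirred_tank():
    return b.ReactorGeometry("cstr", "cstr", 1.0, (1.0,))


@pytest.fixture
def plugflow_scenario(packed_bed):
    """Factory for plug-flow scenarios over the default 8-HRT design."""

    def make(n, k, noise_rel=0.0, seed=0, mix=None, feed=None, **kw):
        return b.SyntheticScenario(
            geometry=packed_bed,
            true_n=n,
            true_k=k,
            route_mix=mix or b.RouteMix({"eq3": 1.0}),
            feed=feed or {"sulfate": 1000.0, "lactate": 2000.0, "acetate": 0.0},
            noise_rel=noise_rel,
            seed=seed,
            **kw,
        )

    return make
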