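import numpy as np
import pytest

from spam import (
    VesselSpec,
    build_frame,
    fit_boundary_spline,
    make_vessel,
    sample_chain,
)


@pytest.fixture(scope="session")
def arch_spec():
    """Compact curved-vessel spec, fast enough for session-wide reuse."""
    return VesselSpec(
        arc_radius=60.0,
        straight_length=90.0,
        half_width=12.0,
        image_size=(200, 220),
        boundary_spacing=15.0,
        noise_sd=1.0,
    )


@pytest.fixture(scope="session")
def arch_vessel(arch_spec):
    return make_vessel(arch_spec, seed=7)


@pytest.fixture(scope="session")
def arch_chains(arch_vessel):
    ca = sample_chain(fit_boundary_spline(arch_vessel.boundary_a))
    cb = sample_chain(fit_boundary_spline(arch_vessel.boundary_b))
    return ca, cb


@pytest.fixture(scope="session")
def arch_frame(arch_chains):
    return build_frame(*arch_chains)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
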