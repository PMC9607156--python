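"""Shared fixtures: small synthetic systems sized for fast tests."""

import pytest

from ldtk import SyntheticSpec, generate_trilayer, generate_trilayer_trajectory


def small_spec(**overrides) -> SyntheticSpec:
    """A reduced trilayer that keeps every feature of the full system."""
    base = dict(
        seed=11,
        box=(6.0, 6.0, 14.0),
        n_chyo=80,
        n_tg=16,
        n_pl_per_leaflet=50,
        surf_tg_fraction=0.25,
        core_half_thickness=3.5,
        water_density_slab=0.2,
    )
    base.update(overrides)
    return SyntheticSpec(**base)


@pytest.fixture(scope="session")
def trilayer():
    return generate_trilayer(small_spec())


@pytest.fixture(scope="session")
def trajectory():
    return generate_trilayer_trajectory(small_spec(), n_frames=8, dt=1.0)
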