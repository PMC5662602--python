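import pytest

from polygea import build_polyamine_minimodel


@pytest.fixture(scope="session")
def minimodel():
    """Uncorrected mini-model with polyamines in biomass (Table-1 conditions)."""
    return build_polyamine_minimodel(
        corrected_pnp=False, include_polyamines_in_biomass=True
    )


@pytest.fixture(scope="session")
def corrected_minimodel():
    """PNP-corrected mini-model with polyamines in biomass (Table-2 conditions)."""
    return build_polyamine_minimodel(
        corrected_pnp=True, include_polyamines_in_biomass=True
    )


@pytest.fixture(scope="session")
def base_minimodel():
    """Mini-model with the unamended biomass (no polyamine demand)."""
    return build_polyamine_minimodel(
        corrected_pnp=False, include_polyamines_in_biomass=False
    )
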