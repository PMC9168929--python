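import pytest

from ch4context import AtmosphereState, MeltingScenario, PlanetContext, TriState


@pytest.fixture
def reference_scenario() -> MeltingScenario:
    """Mid-range magmatic conditions at the terrestrial-basalt temperature."""
    return MeltingScenario(
        pressure=0.25,
        temperature=1420.0,
        delta_iw=0.0,
        source_co2=200e-6,
        source_h2o=1e-3,
        melt_fraction=0.1,
    )


@pytest.fixture
def archean_context() -> PlanetContext:
    """Archean-Earth-like planet: every framework criterion should pass."""
    atm = AtmosphereState(
        f_ch4=5e-3,
        f_co2=0.1,
        f_co=5e-4,  # CO/CH4 = 0.1
        f_o2=0.0,
    )
    return PlanetContext(
        atmosphere=atm,
        bulk_density_terrestrial=TriState.TRUE,
        in_habitable_zone=TriState.TRUE,
        high_mean_molecular_weight_atm=TriState.TRUE,
        anoxic=TriState.TRUE,
        stellar_age=4.5e9,
        water_mass_fraction_estimate=2.5e-4,
    )
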