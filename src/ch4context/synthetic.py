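"""Synthetic planet-scenario ensembles for end-to-end testing.

Each archetype draws a coherent bundle — a :class:`PlanetContext`, and where
relevant a :class:`MeltingScenario` or :class:`PlanetVolatileInventory` —
from distributions matching the parameter ranges the analysis assumes:

* ``archean_inhabited`` — anoxic N2-CO2 world with a methane-cycling
  biosphere: f_CH4 log-uniform in [1e-3, 1e-2], CO/CH4 log-uniform in
  [0.03, 0.3], CO2 present, old Sun-like star, terrestrial density.
* ``reduced_mantle_world`` — Mercury-like interior, ΔIW uniform in
  [-11, -2]; graphite sequestration starves the gas phase, so trace CH4
  and a CO-rich atmosphere.
* ``serpentinizing_world`` — abiotic water-rock CH4 only: trace mixing
  ratios whose implied fluxes sit below the ~10 Tmol/y abiotic ceiling,
  with high CO/CH4.
* ``melted_exotitan`` — Earth-mass planet with a melted Titan-like volatile
  inventory: water mass fraction log-uniform in [1e-4, 1e-1], CH4 inventory
  fraction uniform in [1e-4, 1e-2], 10% atmospheric CH4.
* ``oxic_inhabited`` — modern-Earth-like O2-rich atmosphere with trace CH4.
* ``h2_dominated`` — low mean-molecular-weight envelope; methane long-lived
  for abiotic reasons, gating criterion fails.

Ranges without a stated anchor are test fixtures chosen for coverage, not
science claims. Generation is fully reproducible under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assessment import PlanetContext, TriState
from .escape import PlanetVolatileInventory
from .fluxbalance import AtmosphereState
from .geochem import MeltingScenario

__all__ = ["Scenario", "ScenarioEnsemble", "ARCHETYPES", "generate"]

ARCHETYPES = (
    "archean_inhabited",
    "reduced_mantle_world",
    "serpentinizing_world",
    "melted_exotitan",
    "oxic_inhabited",
    "h2_dominated",
)


@dataclass(frozen=True)
class Scenario:
    context: PlanetContext
    melting: MeltingScenario | None = None
    inventory: PlanetVolatileInventory | None = None


@dataclass(frozen=True)
class ScenarioEnsemble:
    archetype: str
    seed: int
    scenarios: tuple[Scenario, ...]

    def __len__(self) -> int:
        return len(self.scenarios)


def _logu(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10.0 ** rng.uniform(np.log10(lo), np.log10(hi)))


def _archean_inhabited(rng: np.random.Generator) -> Scenario:
    f_ch4 = _logu(rng, 1e-3, 1e-2)
    co_ch4 = _logu(rng, 0.03, 0.3)
    atm = AtmosphereState(
        f_ch4=f_ch4,
        f_co=co_ch4 * f_ch4,
        f_co2=float(rng.uniform(0.02, 0.2)),
        f_o2=0.0,
        f_h2=_logu(rng, 1e-4, 1e-3),
    )
    ctx = PlanetContext(
        atmosphere=atm,
        bulk_density_terrestrial=TriState.TRUE,
        in_habitable_zone=TriState.TRUE,
        high_mean_molecular_weight_atm=TriState.TRUE,
        anoxic=TriState.TRUE,
        stellar_age=float(rng.uniform(2e9, 6e9)),
        water_mass_fraction_estimate=_logu(rng, 1e-4, 5e-3),
    )
    return Scenario(context=ctx)


def _reduced_mantle_world(rng: np.random.Generator) -> Scenario:
    melting = MeltingScenario(
        pressure=float(rng.uniform(0.0, 0.5)),
        temperature=float(rng.uniform(1400.0, 1445.0)),
        delta_iw=float(rng.uniform(-11.0, -2.0)),
        source_co2=_logu(rng, 50e-6, 1000e-6),
        source_h2o=_logu(rng, 1e-4, 5e-3),
        melt_fraction=float(rng.uniform(0.05, 0.3)),
        melt_production=_logu(rng, 1.0, 100.0),
    )
    f_ch4 = _logu(rng, 1e-8, 1e-6)
    atm = AtmosphereState(
        f_ch4=f_ch4,
        f_co=min(1.0, _logu(rng, 10.0, 1000.0) * f_ch4),
        f_co2=float(rng.uniform(0.01, 0.1)),
        f_o2=0.0,
    )
    ctx = PlanetContext(
        atmosphere=atm,
        bulk_density_terrestrial=TriState.TRUE,
        in_habitable_zone=TriState.TRUE,
        high_mean_molecular_weight_atm=TriState.TRUE,
        anoxic=TriState.TRUE,
        stellar_age=float(rng.uniform(1e9, 8e9)),
        water_mass_fraction_estimate=_logu(rng, 1e-5, 1e-3),
    )
    return Scenario(context=ctx, melting=melting)


def _serpentinizing_world(rng: np.random.Generator) -> Scenario:
    f_ch4 = _logu(rng, 1e-6, 5e-5)
    atm = AtmosphereState(
        f_ch4=f_ch4,
        f_co=min(1.0, _logu(rng, 1.0, 100.0) * f_ch4),
        f_co2=float(rng.uniform(0.01, 0.2)),
        f_o2=0.0,
    )
    ctx = PlanetContext(
        atmosphere=atm,
        bulk_density_terrestrial=TriState.TRUE,
        in_habitable_zone=TriState.TRUE,
        high_mean_molecular_weight_atm=TriState.TRUE,
        anoxic=TriState.TRUE,
        stellar_age=float(rng.uniform(1e9, 8e9)),
        water_mass_fraction_estimate=_logu(rng, 1e-4, 1e-2),
    )
    return Scenario(context=ctx)


def _melted_exotitan(rng: np.random.Generator) -> Scenario:
    inventory = PlanetVolatileInventory(
        water_mass_fraction=_logu(rng, 1e-4, 1e-1),
        ch4_inventory_fraction=float(rng.uniform(1e-4, 1e-2)),
        ch4_mixing_ratio=0.10,
    )
    atm = AtmosphereState(
        f_ch4=0.10,
        f_co2=float(rng.uniform(0.05, 0.3)),
        f_o2=0.0,
    )
    water = inventory.water_mass_fraction
    ctx = PlanetContext(
        atmosphere=atm,
        # a >1 wt% water envelope is resolvable as a low bulk density
        bulk_density_terrestrial=TriState.from_bool(water < 0.01),
        in_habitable_zone=TriState.TRUE,
        high_mean_molecular_weight_atm=TriState.TRUE,
        anoxic=TriState.TRUE,
        stellar_age=float(rng.uniform(1e9, 5e9)),
        water_mass_fraction_estimate=water,
    )
    return Scenario(context=ctx, inventory=inventory)


def _oxic_inhabited(rng: np.random.Generator) -> Scenario:
    atm = AtmosphereState(
        f_ch4=_logu(rng, 1e-7, 1e-5),
        f_co=_logu(rng, 1e-8, 1e-7),
        f_co2=float(rng.uniform(1e-4, 1e-2)),
        f_o2=float(rng.uniform(0.05, 0.3)),
    )
    ctx = PlanetContext(
        atmosphere=atm,
        bulk_density_terrestrial=TriState.TRUE,
        in_habitable_zone=TriState.TRUE,
        high_mean_molecular_weight_atm=TriState.TRUE,
        anoxic=TriState.FALSE,
        stellar_age=float(rng.uniform(2e9, 8e9)),
        water_mass_fraction_estimate=_logu(rng, 1e-4, 1e-3),
    )
    return Scenario(context=ctx)


def _h2_dominated(rng: np.random.Generator) -> Scenario:
    atm = AtmosphereState(
        mean_molar_mass=0.004,
        f_ch4=_logu(rng, 1e-4, 1e-2),
        f_co2=_logu(rng, 1e-5, 1e-3),
        f_h2=float(rng.uniform(0.6, 0.9)),
    )
    ctx = PlanetContext(
        atmosphere=atm,
        bulk_density_terrestrial=TriState.FALSE,
        in_habitable_zone=TriState.TRUE,
        high_mean_molecular_weight_atm=TriState.FALSE,
        anoxic=TriState.TRUE,
        stellar_age=float(rng.uniform(1e9, 8e9)),
        water_mass_fraction_estimate=None,
    )
    return Scenario(context=ctx)


_GENERATORS = {
    "archean_inhabited": _archean_inhabited,
    "reduced_mantle_world": _reduced_mantle_world,
    "serpentinizing_world": _serpentinizing_world,
    "melted_exotitan": _melted_exotitan,
    "oxic_inhabited": _oxic_inhabited,
    "h2_dominated": _h2_dominated,
}


def generate(archetype: str, n: int, seed: int) -> ScenarioEnsemble:
    """Draw ``n`` scenarios of the given archetype, reproducibly.

    Raises ``ValueError`` for an unknown archetype or ``n`` < 1.
    """
    if archetype not in _GENERATORS:
        raise ValueError(
            f"unknown archetype {archetype!r}; choose from {ARCHETYPES}"
        )
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    gen = _GENERATORS[archetype]
    return ScenarioEnsemble(
        archetype=archetype,
        seed=seed,
        scenarios=tuple(gen(rng) for _ in range(n)),
    )
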