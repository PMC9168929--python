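"""Atmospheric CH4 lifetime on melted exo-Titans via diffusion-limited escape.

An Earth-mass planet that accreted a Titan-like volatile inventory and then
migrated into the habitable zone melts its ice and carries a massive
CH4/CO2/H2O reservoir. Methane photolysis liberates hydrogen, which escapes
at the diffusion limit through the background (N2) atmosphere; each CH4
destroyed irreversibly exports 4 H atoms. With the atmospheric CH4 mixing
ratio held at a steady 10% (a conservative choice given the relative
solubilities of CH4 and CO2), the reservoir lifetime is

    tau = N_CH4 / (Phi_H / 4 * A),   Phi_H = b * (4 f_CH4) / H_a,

where N_CH4 is the total methane inventory in molecules, A the planet
surface area, b the binary diffusion parameter for atomic H in N2, and H_a
the background-atmosphere scale height at the homopause. tau is therefore
exactly proportional to water_mass_fraction x ch4_inventory_fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import pandas as pd

from .constants import (
    AVOGADRO,
    BOLTZMANN,
    EARTH_MASS,
    EARTH_RADIUS,
    GRAVITATIONAL_CONSTANT,
    MOLAR_MASS_CH4,
    MOLAR_MASS_N2,
    SECONDS_PER_YEAR,
)

__all__ = [
    "PlanetVolatileInventory",
    "EscapeModel",
    "binary_diffusion_h_n2",
    "diffusion_limited_h_flux",
    "ch4_lifetime",
    "lifetime_grid",
]

FOUR_PI = 4.0 * 3.141592653589793


def binary_diffusion_h_n2(temperature: float) -> float:
    """Binary diffusion parameter b for atomic H in N2, in m^-1 s^-1.

    Marrero & Mason (1972) tabulation, b = 4.87e17 T^0.698 cm^-1 s^-1,
    converted to SI. ~2.0e21 m^-1 s^-1 at 200 K.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return 4.87e17 * temperature**0.698 * 100.0


@dataclass(frozen=True)
class PlanetVolatileInventory:
    """Volatile inventory of an Earth-mass melted exo-Titan.

    ``water_mass_fraction`` is the water reservoir relative to planet mass
    (0.01-10 wt% explored); ``ch4_inventory_fraction`` the CH4 mass relative
    to the water mass (Titan's is ~0.35%); ``ch4_mixing_ratio`` the fixed
    steady-state atmospheric mixing ratio (default 10%).
    """

    water_mass_fraction: float
    ch4_inventory_fraction: float
    ch4_mixing_ratio: float = 0.10
    planet_mass: float = EARTH_MASS
    planet_radius: float = EARTH_RADIUS

    def __post_init__(self) -> None:
        for name in (
            "water_mass_fraction",
            "ch4_inventory_fraction",
            "planet_mass",
            "planet_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.ch4_mixing_ratio < 1.0):
            raise ValueError("ch4_mixing_ratio must be in (0, 1)")

    @property
    def surface_gravity(self) -> float:
        return GRAVITATIONAL_CONSTANT * self.planet_mass / self.planet_radius**2

    @property
    def ch4_molecules(self) -> float:
        """Total CH4 reservoir in molecules."""
        ch4_mass = self.water_mass_fraction * self.planet_mass * self.ch4_inventory_fraction
        return ch4_mass / (MOLAR_MASS_CH4 / AVOGADRO)


@dataclass(frozen=True)
class EscapeModel:
    """Constants of the diffusion-limited hydrogen escape calculation.

    Defaults: 200 K homopause, N2 background, atomic-H binary diffusion
    parameter evaluated at the homopause temperature, and 4 H atoms lost
    per CH4 destroyed (OH oxidation neglected, so every methane carbon is
    oxidised only after its hydrogen has been exported).
    """

    homopause_temperature: float = 200.0
    background_molar_mass: float = MOLAR_MASS_N2
    h_atoms_per_ch4: int = 4
    binary_diffusion_b: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.binary_diffusion_b == 0.0:
            object.__setattr__(
                self,
                "binary_diffusion_b",
                binary_diffusion_h_n2(self.homopause_temperature),
            )
        for name in (
            "homopause_temperature",
            "background_molar_mass",
            "h_atoms_per_ch4",
            "binary_diffusion_b",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def scale_height(self, gravity: float) -> float:
        """Background-atmosphere scale height kT/(m g) at the homopause, m."""
        m = self.background_molar_mass / AVOGADRO
        return BOLTZMANN * self.homopause_temperature / (m * gravity)


def diffusion_limited_h_flux(
    f_ch4: float, model: EscapeModel | None = None, gravity: float | None = None
) -> float:
    """Diffusion-limited escape flux of hydrogen atoms, m^-2 s^-1.

    ``Phi = b f_H / H_a`` with the total hydrogen mixing ratio
    ``f_H = h_atoms_per_ch4 * f_ch4`` (CH4 the only hydrogen carrier).
    Linear in ``f_ch4``; zero methane gives zero flux.
    """
    if not (0.0 <= f_ch4 < 1.0):
        raise ValueError("f_ch4 must be in [0, 1)")
    model = model or EscapeModel()
    if gravity is None:
        gravity = GRAVITATIONAL_CONSTANT * EARTH_MASS / EARTH_RADIUS**2
    f_h = model.h_atoms_per_ch4 * f_ch4
    return model.binary_diffusion_b * f_h / model.scale_height(gravity)


def ch4_lifetime(
    inventory: PlanetVolatileInventory, model: EscapeModel | None = None
) -> float:
    """Years to exhaust the CH4 reservoir at the diffusion-limited loss rate.

    The global CH4 destruction rate is the escaping H flux divided by the
    per-molecule stoichiometry, times the planet surface area. Because the
    mixing ratio is held fixed, the lifetime is exactly separable:
    proportional to both water_mass_fraction and ch4_inventory_fraction.
    """
    model = model or EscapeModel()
    phi_h = diffusion_limited_h_flux(
        inventory.ch4_mixing_ratio, model, inventory.surface_gravity
    )
    area = FOUR_PI * inventory.planet_radius**2
    ch4_loss_per_s = phi_h / model.h_atoms_per_ch4 * area
    return inventory.ch4_molecules / ch4_loss_per_s / SECONDS_PER_YEAR


def lifetime_grid(
    water_fracs, inv_fracs, model: EscapeModel | None = None
) -> pd.DataFrame:
    """Tabulate CH4 lifetimes over water-mass and inventory-fraction grids.

    Returns a DataFrame with columns ``water_mass_fraction``,
    ``ch4_inventory_fraction`` and ``lifetime_years``; lifetimes increase
    monotonically along both axes.
    """
    water_fracs = list(water_fracs)
    inv_fracs = list(inv_fracs)
    if not water_fracs or not inv_fracs:
        raise ValueError("grids must be non-empty")
    model = model or EscapeModel()
    rows = [
        {
            "water_mass_fraction": w,
            "ch4_inventory_fraction": x,
            "lifetime_years": ch4_lifetime(
                PlanetVolatileInventory(w, x), model
            ),
        }
        for w, x in product(water_fracs, inv_fracs)
    ]
    return pd.DataFrame(rows)
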