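"""0-D flux balance: from observed CH4 abundance to required surface flux.

Methane is photochemically short-lived in high mean-molecular-weight
atmospheres, so a measured mixing ratio implies a replenishment flux. This
module converts a mixing ratio to a column density and divides by a kinetic
lifetime to obtain the implied global surface flux in Tmol/y, which can then
be compared with the modern biogenic benchmark (30 Tmol/y) and the ceiling
on known abiotic production (~10 Tmol/y).

Lifetime presets encode the regimes discussed in the literature: ~10 y for
O2-rich atmospheres (CH4 + O2 kinetic instability) and 2,000-20,000 y for
weakly reduced Archean-like atmospheres.

Unknown mixing ratios propagate as ``None`` (never silently as zero); the
assessment layer consumes that tri-state.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import (
    AVOGADRO,
    EARTH_RADIUS,
    MOLAR_MASS_N2,
    earth_surface_gravity,
)

__all__ = [
    "AtmosphereState",
    "LifetimePreset",
    "LIFETIME_PRESETS",
    "column_density",
    "implied_surface_flux",
]

_FOUR_PI = 4.0 * 3.141592653589793
_SPECIES = ("f_ch4", "f_co2", "f_co", "f_o2", "f_h2")


@dataclass(frozen=True)
class AtmosphereState:
    """Observable atmospheric composition; ``None`` marks an unmeasured species."""

    surface_pressure: float = 1.01325e5  # Pa
    mean_molar_mass: float = MOLAR_MASS_N2  # kg/mol
    gravity: float = earth_surface_gravity  # m/s^2
    planet_radius: float = EARTH_RADIUS  # m
    f_ch4: float | None = None
    f_co2: float | None = None
    f_co: float | None = None
    f_o2: float | None = None
    f_h2: float | None = None

    def __post_init__(self) -> None:
        if self.surface_pressure <= 0:
            raise ValueError("surface_pressure must be positive")
        if self.mean_molar_mass <= 0 or self.gravity <= 0 or self.planet_radius <= 0:
            raise ValueError("mean_molar_mass, gravity and planet_radius must be positive")
        total = 0.0
        for name in _SPECIES:
            v = getattr(self, name)
            if v is None:
                continue
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
            total += v
        if total > 1.0 + 1e-12:
            raise ValueError(f"known mixing ratios sum to {total} > 1")

    def co_ch4_ratio(self) -> float | None:
        """CO/CH4 ratio, or ``None`` if either species is unmeasured."""
        if self.f_co is None or self.f_ch4 is None or self.f_ch4 == 0.0:
            return None
        return self.f_co / self.f_ch4


@dataclass(frozen=True)
class LifetimePreset:
    regime: str
    lifetime: float  # years

    def __post_init__(self) -> None:
        if self.lifetime <= 0:
            raise ValueError("lifetime must be positive")


#: Kinetic CH4 lifetime regimes (years).
LIFETIME_PRESETS: dict[str, LifetimePreset] = {
    "oxic": LifetimePreset("oxic", 10.0),
    "anoxic_archean_low": LifetimePreset("anoxic_archean_low", 2_000.0),
    "anoxic_archean_high": LifetimePreset("anoxic_archean_high", 20_000.0),
}


def column_density(atm: AtmosphereState, mixing_ratio: float | None) -> float | None:
    """Vertical column of a species in molecules/m^2, or ``None`` if unknown.

    Hydrostatic column: ``N = f P / (m̄ g)`` with m̄ the mean molecular mass
    ``mean_molar_mass / N_A``. Linear in both f and P.
    """
    if mixing_ratio is None:
        return None
    if not (0.0 <= mixing_ratio <= 1.0):
        raise ValueError("mixing_ratio must be in [0, 1]")
    m_mean = atm.mean_molar_mass / AVOGADRO
    return mixing_ratio * atm.surface_pressure / (m_mean * atm.gravity)


def implied_surface_flux(
    atm: AtmosphereState, lifetime: float | LifetimePreset
) -> float | None:
    """Global CH4 replenishment flux (Tmol/y) implied by steady state.

    ``flux = column x area / (lifetime x N_A)``: the column inventory must
    be resupplied once per kinetic lifetime. Returns ``None`` when the CH4
    mixing ratio is unmeasured.

    Raises
    ------
    ValueError
        If the lifetime is not positive.
    """
    if isinstance(lifetime, LifetimePreset):
        lifetime = lifetime.lifetime
    if lifetime <= 0:
        raise ValueError("lifetime must be positive")
    col = column_density(atm, atm.f_ch4)
    if col is None:
        return None
    area = _FOUR_PI * atm.planet_radius**2
    mol_per_year = col * area / (lifetime * AVOGADRO)
    return mol_per_year / 1e12
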