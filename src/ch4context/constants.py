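"""Physical and framework constants used across the package.

Physical constants come from :mod:`scipy.constants` (CODATA). Planetary
values are the IAU nominal Earth mass and mean radius. The "framework"
constants encode the decision thresholds of the methane-biosignature
assessment: the modern biogenic CH4 flux, the ceiling on known abiotic
production, the CH4 abundance and CO/CH4 ratio thresholds, and Titan's
volatile CH4 inventory relative to its water.
"""

from scipy import constants as _sc

# --- physical ---------------------------------------------------------------
BOLTZMANN = _sc.k  # J/K
AVOGADRO = _sc.N_A  # 1/mol
GRAVITATIONAL_CONSTANT = _sc.G  # m^3 kg^-1 s^-2

EARTH_MASS = 5.9722e24  # kg
EARTH_RADIUS = 6.371e6  # m (mean)
SECONDS_PER_YEAR = 3.15576e7  # Julian year

MOLAR_MASS_CH4 = 16.043e-3  # kg/mol
MOLAR_MASS_N2 = 28.014e-3  # kg/mol

# --- framework thresholds ---------------------------------------------------
#: Modern global biogenic CH4 emission, Tmol/y.
BIOGENIC_FLUX_MODERN = 30.0
#: Upper bound on what known abiotic processes plausibly sustain, Tmol/y.
ABIOTIC_FLUX_CEILING = 10.0
#: Atmospheric CH4 mixing ratio above which sustained abiotic sourcing is
#: implausible in an anoxic, high-MMW atmosphere.
CH4_ABUNDANCE_THRESHOLD = 1e-3
#: CO/CH4 ratio below which methane-cycling biospheres are favoured.
CO_CH4_RATIO_THRESHOLD = 1.0
#: CO/CH4 ratio regarded as a strong sign of a methane-cycling biosphere.
CO_CH4_STRONG_BIOSPHERE = 0.1
#: Titan's CH4 inventory as a fraction of its water mass.
TITAN_CH4_INVENTORY = 0.0035
#: Water mass fraction above which a melted exo-Titan can sustain CH4 for
#: ~100 My; below it the false-positive window is short.
EXOTITAN_WATER_FRACTION_LIMIT = 0.01
#: Stellar age beyond which impact-generated transient atmospheres have
#: long since decayed, years.
OLD_STAR_AGE = 1e9

earth_surface_gravity = (
    GRAVITATIONAL_CONSTANT * EARTH_MASS / EARTH_RADIUS**2
)  # m/s^2, ~9.82
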