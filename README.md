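# ch4context

Planetary-context assessment of atmospheric methane as an exoplanet
biosignature.

Methane is photochemically short-lived in the high mean-molecular-weight
atmospheres of terrestrial planets, so a detected CH4 abundance implies a
large, continuous surface source — on Earth, overwhelmingly biological
(~30 Tmol/y). But abiotic pathways exist: magmatic outgassing from reduced
mantles, serpentinization and other water–rock reactions, impact-delivered
volatiles, and migrated Titan-like worlds whose melted ice supplies a
massive CH4 reservoir. `ch4context` provides the quantitative machinery to
weigh these alternatives for a given planet scenario. It is aimed at
astrobiologists and exoplanet observers triaging methane detections.

## What it computes

* **Graphite sequestration** (`ch4context.geochem`) — a batch-melting
  volatile-partitioning model in which the melt's dissolved carbon is
  capped by oxygen-fugacity-dependent graphite saturation
  (C + O2 ⇌ CO2(melt), unit slope in log10 fO2). Monte Carlo propagation
  over pressure (0–0.5 GPa), solidus temperature (1,400–1,445 K), source
  CO2/H2O and melt fraction yields the fraction of source carbon retained
  as graphite versus ΔIW (log10 fO2 relative to the iron–wüstite buffer).
  At or below IW−2, >99% of carbon never reaches the gas phase — very
  reduced mantles cannot outgas much CH4.
* **Exo-Titan lifetimes** (`ch4context.escape`) — diffusion-limited
  hydrogen escape, Φ = b·f_H/H_a with f_H = 4·f_CH4, drains the CH4
  reservoir of an Earth-mass planet with a melted Titan-like volatile
  inventory. The lifetime is exactly separable,
  τ ∝ (water mass fraction) × (CH4 inventory fraction).
* **Flux balance** (`ch4context.fluxbalance`) — a 0-D column/lifetime
  balance, flux = N_CH4 · A / (τ · N_A), converting an observed mixing
  ratio plus a kinetic-lifetime regime (10 y oxic; 2,000–20,000 y anoxic
  Archean-like) into the implied global replenishment flux in Tmol/y.
* **Abiotic source compendium** (`ch4context.compendium`) — a
  machine-readable catalogue of known abiotic CH4 sources with min/max
  global flux estimates and provenance; no entry approaches the modern
  biogenic 30 Tmol/y.
* **Assessment** (`ch4context.assessment`) — a tri-state rule engine
  combining gating context (terrestrial density, habitable zone, high-MMW
  atmosphere, anoxia) and evidence criteria (CH4 > 1e−3, implied flux
  above the ~10 Tmol/y abiotic ceiling, CO2 present, CO/CH4 < 1, water
  fraction < 1 wt%, old host star) into an ordered verdict; unknowns cap
  the verdict rather than defaulting optimistic.
* **Synthetic ensembles** (`ch4context.synthetic`) — seeded scenario
  generators (Archean-inhabited, reduced-mantle, serpentinizing,
  melted exo-Titan, oxic, H2-dominated) for end-to-end testing.

## Worked example

```python
from ch4context import (
    AtmosphereState, PlanetContext, PlanetVolatileInventory, TriState,
    assess, ch4_lifetime, implied_surface_flux, monte_carlo_graphite_curve,
)
from ch4context.fluxbalance import LIFETIME_PRESETS

# How long does methane survive on a melted exo-Titan?
tau = ch4_lifetime(PlanetVolatileInventory(
    water_mass_fraction=0.01, ch4_inventory_fraction=0.0035))
print(f"lifetime at 1 wt% water: {tau/1e6:.1f} My")

# What surface flux does an Archean-like CH4 abundance demand?
atm = AtmosphereState(f_ch4=5e-3, f_co2=0.1, f_co=5e-4, f_o2=0.0)
flux = implied_surface_flux(atm, LIFETIME_PRESETS["anoxic_archean_low"])
print(f"implied flux: {flux:.0f} Tmol/y")

# Does the full context support a biological reading?
ctx = PlanetContext(
    atmosphere=atm,
    bulk_density_terrestrial=TriState.TRUE,
    in_habitable_zone=TriState.TRUE,
    high_mean_molecular_weight_atm=TriState.TRUE,
    anoxic=TriState.TRUE,
    stellar_age=4.5e9,
    water_mass_fraction_estimate=2.5e-4,
)
print(assess(ctx, flux).verdict.name)

# Graphite sequestration curve under reduced magmatic conditions
mc = monte_carlo_graphite_curve(n_draws=10_000, seed=0)
row = dict(zip(mc.delta_iw_grid, mc.mean_graphite_fraction))
print(f"graphite fraction at IW-2: {row[-2.0]:.4f}")
```

prints

```
lifetime at 1 wt% water: 15.0 My
implied flux: 470 Tmol/y
CANDIDATE_BIOSIGNATURE_SEEK_CORROBORATION
graphite fraction at IW-2: 1.0000
```

A 1 wt%-water exo-Titan loses its methane within ~15 My — far shorter than
stellar ages, so a long-lived false positive requires a water-rich planet
observable through its low bulk density. The Archean-analog abundance
demands hundreds of Tmol/y, an order of magnitude beyond any catalogued
abiotic source, and with every contextual criterion passing the scenario
classifies as a candidate biosignature warranting corroboration. At IW−2,
essentially all source carbon is locked in graphite, ruling out
reduced-mantle outgassing as a methane source.

The same operations are exposed on the command line via `ch4context
melt-mc | lifetime-grid | implied-flux | compendium | assess | synth`
(see `ch4context --help`).

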