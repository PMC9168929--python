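# Methods

This note documents the models behind `ch4context`, the parameter choices
that matter, and what the synthetic scenarios do and do not establish.

## Graphite sequestration during partial melting

**Model.** Batch melting: a partial melt of fraction F stays in chemical
equilibrium with its residue until extraction. Water partitions by the
standard relation

    C_melt = C_source / (F + D_H2O (1 − F)),   D_H2O = 0.01,

treating water as a highly incompatible component (the package does not
cite a measured D; 0.01 is the conventional order for hydrous melts and is
exposed as `geochem.D_H2O`). Carbon is treated as fully incompatible in the
crystalline residue (D_C = 0): all source carbon is available to the melt,
but the dissolved amount is capped at the graphite-saturated capacity and
the excess remains behind as graphite. Mass balance is then exact and
closed-form: source carbon = dissolved carbon × F + graphite carbon, which
the tests verify to 1e−12 relative error. Setting D_C = 0 resolves
explicitly how residue carbon is counted — there is none apart from
graphite; a nonzero D_C would shift a few percent of carbon from the
graphite to the residue term without changing the shape of the curve.

**Graphite saturation.** The equilibrium C(graphite) + O2 ⇌ CO2(melt)
implies unit slope of log dissolved carbonate in log10 fO2. Written
relative to the iron–wüstite buffer, the leading temperature and pressure
dependence of the equilibrium constant cancels against that of the buffer,
leaving a one-parameter law

    X_CO2(ΔIW) = X_ref · 10^(ΔIW − ΔIW_ref),

anchored at X_ref = 1 wt% CO2-equivalent at ΔIW_ref = +3.5, the oxidation
state of terrestrial basalts. The anchor makes Earth-like melts
comfortably undersaturated for mantle-like source-carbon contents
(50–1,000 ppm CO2) while melts at or below IW−2 retain >99% of their
carbon as graphite — the two empirical ends the curve must reproduce.
Temperature and pressure still enter absolute-fO2 work through the buffer
conversion, for which the Frost (1991) parameterization is used
(log10 fO2 = 6.702 − 27489/T + 0.055(P_bar − 1)/T, calibrated
1,000–2,500 K; out-of-range inputs raise).

**Monte Carlo.** Per ΔIW grid point (default integer steps −11…+5),
10,000 scenarios are drawn: pressure uniform 0–0.5 GPa, solidus
temperature uniform 1,400–1,445 K, source CO2 log-uniform 50–1,000 ppm,
source H2O log-uniform 0.01–0.5 wt%, melt fraction uniform 0.05–0.3, melt
production log-uniform 1–100 km³/y. The summary reports the mean retained
fraction and a 2.5/97.5-percentile interval. All ranges are a single
dataclass (`ParameterRanges`) and overridable from the CLI config, since
they are defaults bracketing Earth-like mantle values rather than measured
inputs. Under the buffer-relative capacity law the retained fraction
depends only on ΔIW, source CO2 and melt fraction; the other parameters
are drawn anyway to keep the stream faithful to the scenario definition.
Undersaturated draws are assigned exactly zero graphite so the oxidised
end of the curve is exactly 0 rather than float noise.

## Exo-Titan methane lifetimes

An Earth-mass planet with a melted Titan-like volatile inventory holds
N_CH4 = (water mass fraction) × M_planet × (CH4 inventory fraction) /
m_CH4 molecules of methane. Photolysis liberates hydrogen, which escapes
at the diffusion limit through the background atmosphere:

    Φ_H = b · f_H / H_a,   f_H = 4 f_CH4,

with the atmospheric mixing ratio pinned at f_CH4 = 0.10 for the whole
lifetime (a conservative choice: CH4 is far less soluble than CO2, so the
atmosphere stays methane-rich while the reservoir lasts). Four hydrogen
atoms are exported per methane destroyed — OH oxidation is neglected, so
hydrogen loss is the only irreversible sink, again conservative (it
maximises the lifetime per unit escape). The lifetime is

    τ = N_CH4 / (Φ_H/4 · 4πR²),

exactly proportional to water mass fraction × inventory fraction; every
constant is absorbed into one separability coefficient.

Constants: homopause temperature 200 K; N2 background (mean molar mass
0.028 kg/mol) for the scale height — adding the CO2 admixture would
shorten lifetimes by tens of percent, well inside the factor-of-2 band the
anchors are quoted at; binary diffusion parameter for **atomic H in N2**,
b = 4.87e17·T^0.698 cm⁻¹s⁻¹ (Marrero & Mason 1972), ≈2.0e21 m⁻¹s⁻¹ at
200 K, consistent with counting escape in H atoms. Surface gravity comes
from Earth mass and radius; the added water mass is ignored (<10% error
even at 10 wt%). With these defaults a Titan-like inventory (0.35% of the
water mass) gives τ ≈ 15 My at 1 wt% water and ≈150 My at 10 wt% — the
~10/~100 My regimes, with the exact 10× ratio guaranteed by separability.
All constants sit on `EscapeModel` and are overridable.

## Flux balance

A 0-D steady state: the hydrostatic column N = f·P/(m̄·g) must be
replenished once per kinetic lifetime, flux = N·4πR²/(τ·N_A), reported in
Tmol/y. Lifetimes are presets — 10 y for O2-rich atmospheres, 2,000 and
20,000 y bracketing weakly reduced Archean-like atmospheres — because the
full flux–abundance relation requires a 1-D photochemical model, which is
deliberately out of scope; the box model reproduces the threshold logic at
order-of-magnitude fidelity only. For a 1-bar Earth analog at
f_CH4 = 1e−3 the 2,000-y regime implies ≈94 Tmol/y, three times the
modern biogenic flux; even the 20,000-y regime implies ≈9.4 Tmol/y,
essentially at the ~10 Tmol/y ceiling of known abiotic production. An
unmeasured mixing ratio propagates as `None` through every operation —
never silently as zero — and surfaces as an `unknown` criterion downstream.

## Compendium

The abiotic-source catalogue is a packaged CSV, one row per source, with
min/max global flux (Tmol/y, either bound may be absent), category, era
and a provenance sentence naming the study behind each number. Laboratory
serpentinization yields whose implied fluxes exceed the crustal
ferrous-iron supply, and whose organic contamination was never quantified,
carry a `contamination_suspect` flag, store no flux bounds, and are
excluded from `max_abiotic_flux` unless explicitly requested. The
serpentinization maximum is a scalar upper bound; representing the full
published probability distribution is out of scope.

## Assessment rules

Criteria are tri-state (pass/fail/unknown). Four are **gating** —
terrestrial bulk density, habitable-zone orbit, high mean-molecular-weight
atmosphere, anoxic atmosphere — because a failure makes a biological
reading untenable regardless of other evidence. Six are **evidence** —
CH4 mixing ratio > 1e−3; implied flux > 10 Tmol/y; CO2 detected;
CO/CH4 < 1 (with < 0.1 annotated as a strong biosphere sign); water mass
fraction < 1 wt% (excludes the long-lived melted exo-Titan false
positive); stellar age ≥ 1 Gy (an impact-generated transient atmosphere
would have decayed; the 1 Gy threshold is a design choice — transients
persist ≲100 My, so any margin beyond that works, and the value is a named
constant). Verdicts form the ordered lattice

    not_assessable < unlikely_biogenic
        < possible_abiotic_false_positive < candidate_biosignature,

chosen so "strength of the biological case" is monotone: any gating fail →
unlikely_biogenic; all criteria pass → candidate; all unknown →
not_assessable; anything else → possible false positive, with the
hypotheses named by the failing criteria (high CO/CH4 →
reduced-mantle outgassing; sub-ceiling flux → serpentinization; young star
→ impact transient; high water fraction or non-terrestrial density →
melted exo-Titan). Unknowns cap the verdict rather than defaulting
optimistic. `classify` is a pure function of the flag map, and the tests
enumerate gating × evidence combinations exhaustively to check that
upgrading any single flag never weakens the verdict and that every lattice
state is reachable.

## Synthetic scenarios

The generators produce parameter draws with the statistical structure the
analysis assumes — e.g. Archean-inhabited worlds draw f_CH4 log-uniform in
[1e−3, 1e−2] and CO/CH4 log-uniform in [0.03, 0.3]; melted exo-Titans draw
water fraction log-uniform in [1e−4, 1e−1] and inventory fraction uniform
in [1e−4, 1e−2]; reduced-mantle worlds draw ΔIW uniform in [−11, −2].
Ranges without an external anchor (oxic O2 levels, H2-envelope
composition) are test fixtures chosen for coverage, not science claims.
The ensembles contain no observational noise, no retrieval uncertainty and
no correlated systematics, so a passing end-to-end test shows the
pipeline's logic is self-consistent under its own assumptions — not that
real observations of such planets would classify as cleanly.

## Numerical choices and problem sizes

All randomness flows through `numpy.random.default_rng(seed)`; equal seeds
give bit-identical outputs everywhere. The Monte Carlo uses 10,000 draws
per grid point (the mean at any point is stable well inside its 95%
interval against a 10×-larger run; the whole 17-point curve takes well
under a second). Percentile confidence intervals are used rather than
normal approximations because the retained fraction saturates near 0 and 1.
Degenerate inputs fail fast: zero melt fraction, empty grids, empty
catalogues, non-positive lifetimes and out-of-calibration buffer
temperatures all raise with explicit messages.

## Known limitations

* The flux–abundance relation is a box model; stellar-type-dependent
  photochemistry (e.g. the weaker near-UV of M dwarfs) requires an
  external 1-D photochemical code and only shifts the presets.
* Gas speciation of the outgassed phase (CH4/CO/CO2/H2 equilibria),
  degassing kinetics and long-term crustal graphite burial are not
  modelled; the melting module answers only how much carbon reaches the
  melt at all.
* Ocean solubility partitioning, ice-covered exo-Titan variants and
  energy-limited or hydrodynamic escape are outside the escape model.
* The assessment flowchart's branch structure is a reconstruction from the
  stated criteria; alternative orderings of the evidence tier would change
  intermediate labels but not the candidate/unlikely endpoints.
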