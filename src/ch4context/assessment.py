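"""Rule-based assessment of a methane detection as a biosignature.

Methane alone proves nothing: the decision framework asks whether the
planetary context supports a biological interpretation and whether any of
the known false-positive pathways could explain the observation instead.
Criteria come in two tiers:

* **gating** — terrestrial bulk density, habitable-zone orbit, high
  mean-molecular-weight atmosphere, anoxic atmosphere. A failed gate makes
  a biological reading of CH4 untenable.
* **evidence** — CH4 mixing ratio above 1e-3; implied surface flux above
  the ~10 Tmol/y abiotic ceiling; CO2 detected alongside CH4; CO/CH4 < 1
  (with ~0.1 a strong biosphere sign); water mass fraction below 1 wt%
  (rules out a long-lived melted exo-Titan); host star older than the
  impact-transient window.

Every criterion is tri-state (pass/fail/unknown) and unknowns cap the
verdict rather than defaulting optimistic: a candidate call requires every
criterion to pass. Verdicts form a lattice

    not_assessable < unlikely_biogenic
        < possible_abiotic_false_positive
        < candidate_biosignature_seek_corroboration

and ``classify`` is a pure, monotone function of the flags: strengthening
any single criterion (fail->pass or unknown->pass) never weakens the
verdict.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .constants import (
    ABIOTIC_FLUX_CEILING,
    CH4_ABUNDANCE_THRESHOLD,
    CO_CH4_RATIO_THRESHOLD,
    CO_CH4_STRONG_BIOSPHERE,
    EXOTITAN_WATER_FRACTION_LIMIT,
    OLD_STAR_AGE,
)
from .fluxbalance import AtmosphereState

__all__ = [
    "TriState",
    "CriterionStatus",
    "Verdict",
    "PlanetContext",
    "AssessmentVerdict",
    "GATING_CRITERIA",
    "EVIDENCE_CRITERIA",
    "evaluate_criteria",
    "classify",
    "assess",
]


class TriState(enum.Enum):
    TRUE = "true"
    FALSE = "false"
    UNKNOWN = "unknown"

    @classmethod
    def from_bool(cls, value: bool | None) -> "TriState":
        if value is None:
            return cls.UNKNOWN
        return cls.TRUE if value else cls.FALSE


class CriterionStatus(enum.Enum):
    PASS = "pass"
    FAIL = "fail"
    UNKNOWN = "unknown"


class Verdict(enum.IntEnum):
    """Ordered verdict lattice; higher is stronger evidence for biology."""

    NOT_ASSESSABLE = 0
    UNLIKELY_BIOGENIC = 1
    POSSIBLE_ABIOTIC_FALSE_POSITIVE = 2
    CANDIDATE_BIOSIGNATURE_SEEK_CORROBORATION = 3


GATING_CRITERIA = (
    "terrestrial_density",
    "habitable_zone",
    "high_mmw_atmosphere",
    "anoxic",
)
EVIDENCE_CRITERIA = (
    "ch4_abundant",
    "flux_exceeds_abiotic",
    "co2_detected",
    "co_ch4_low",
    "low_water_fraction",
    "old_star",
)
ALL_CRITERIA = GATING_CRITERIA + EVIDENCE_CRITERIA

#: False-positive hypotheses triggered by specific failed criteria.
_HYPOTHESES = {
    "co_ch4_low": "reduced_mantle_outgassing",
    "flux_exceeds_abiotic": "serpentinization",
    "old_star": "impact_transient",
    "low_water_fraction": "melted_exotitan",
    "terrestrial_density": "melted_exotitan",
}


@dataclass(frozen=True)
class PlanetContext:
    """Everything known (or not) about the planet hosting the CH4 detection."""

    atmosphere: AtmosphereState
    bulk_density_terrestrial: TriState = TriState.UNKNOWN
    in_habitable_zone: TriState = TriState.UNKNOWN
    high_mean_molecular_weight_atm: TriState = TriState.UNKNOWN
    anoxic: TriState = TriState.UNKNOWN
    stellar_age: float | None = None  # years
    water_mass_fraction_estimate: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "bulk_density_terrestrial",
            "in_habitable_zone",
            "high_mean_molecular_weight_atm",
            "anoxic",
        ):
            if not isinstance(getattr(self, name), TriState):
                raise TypeError(f"{name} must be a TriState")


@dataclass(frozen=True)
class AssessmentVerdict:
    verdict: Verdict
    criteria_flags: dict[str, CriterionStatus]
    notes: tuple[str, ...] = field(default=())


def _tri_to_status(t: TriState) -> CriterionStatus:
    return {
        TriState.TRUE: CriterionStatus.PASS,
        TriState.FALSE: CriterionStatus.FAIL,
        TriState.UNKNOWN: CriterionStatus.UNKNOWN,
    }[t]


def _threshold(value: float | None, threshold: float, above: bool) -> CriterionStatus:
    if value is None:
        return CriterionStatus.UNKNOWN
    ok = value > threshold if above else value < threshold
    return CriterionStatus.PASS if ok else CriterionStatus.FAIL


def evaluate_criteria(
    ctx: PlanetContext, implied_flux: float | None = None
) -> dict[str, CriterionStatus]:
    """Evaluate every framework criterion as pass/fail/unknown.

    ``implied_flux`` is the CH4 replenishment flux in Tmol/y from the flux
    balance (``None`` when the abundance or lifetime regime is unknown).
    Unknown inputs propagate to unknown flags; nothing raises.
    """
    atm = ctx.atmosphere
    flags: dict[str, CriterionStatus] = {
        "terrestrial_density": _tri_to_status(ctx.bulk_density_terrestrial),
        "habitable_zone": _tri_to_status(ctx.in_habitable_zone),
        "high_mmw_atmosphere": _tri_to_status(ctx.high_mean_molecular_weight_atm),
        "anoxic": _tri_to_status(ctx.anoxic),
        "ch4_abundant": _threshold(atm.f_ch4, CH4_ABUNDANCE_THRESHOLD, above=True),
        "flux_exceeds_abiotic": _threshold(implied_flux, ABIOTIC_FLUX_CEILING, above=True),
        "co2_detected": _threshold(atm.f_co2, 0.0, above=True),
        "co_ch4_low": _threshold(atm.co_ch4_ratio(), CO_CH4_RATIO_THRESHOLD, above=False),
        "low_water_fraction": _threshold(
            ctx.water_mass_fraction_estimate, EXOTITAN_WATER_FRACTION_LIMIT, above=False
        ),
        "old_star": (
            CriterionStatus.UNKNOWN
            if ctx.stellar_age is None
            else CriterionStatus.PASS
            if ctx.stellar_age >= OLD_STAR_AGE
            else CriterionStatus.FAIL
        ),
    }
    return flags


def classify(flags: dict[str, CriterionStatus]) -> AssessmentVerdict:
    """Map a complete flag set to a verdict on the lattice.

    * any gating criterion fails -> ``UNLIKELY_BIOGENIC``;
    * every criterion passes -> ``CANDIDATE_BIOSIGNATURE_SEEK_CORROBORATION``;
    * every criterion unknown -> ``NOT_ASSESSABLE``;
    * anything else (evidence failures, partial knowledge) ->
      ``POSSIBLE_ABIOTIC_FALSE_POSITIVE`` with the false-positive
      hypotheses named by the failing criteria.

    Raises ``KeyError`` on a missing flag; pure in its input.
    """
    missing = [c for c in ALL_CRITERIA if c not in flags]
    if missing:
        raise KeyError(f"missing criteria flags: {missing}")

    statuses = [flags[c] for c in ALL_CRITERIA]
    notes = tuple(
        sorted(
            {
                _HYPOTHESES[c]
                for c in ALL_CRITERIA
                if c in _HYPOTHESES and flags[c] == CriterionStatus.FAIL
            }
        )
    )

    if any(flags[c] == CriterionStatus.FAIL for c in GATING_CRITERIA):
        verdict = Verdict.UNLIKELY_BIOGENIC
    elif all(s == CriterionStatus.PASS for s in statuses):
        verdict = Verdict.CANDIDATE_BIOSIGNATURE_SEEK_CORROBORATION
    elif all(s == CriterionStatus.UNKNOWN for s in statuses):
        verdict = Verdict.NOT_ASSESSABLE
    else:
        verdict = Verdict.POSSIBLE_ABIOTIC_FALSE_POSITIVE

    return AssessmentVerdict(
        verdict=verdict, criteria_flags=dict(flags), notes=notes
    )


def assess(
    ctx: PlanetContext, implied_flux: float | None = None
) -> AssessmentVerdict:
    """Evaluate criteria and classify in one step, with annotation notes.

    Adds the ``co_ch4_strong_biosphere_sign`` annotation when the measured
    CO/CH4 ratio falls below ~0.1.
    """
    flags = evaluate_criteria(ctx, implied_flux)
    result = classify(flags)
    ratio = ctx.atmosphere.co_ch4_ratio()
    if ratio is not None and ratio < CO_CH4_STRONG_BIOSPHERE:
        result = AssessmentVerdict(
            verdict=result.verdict,
            criteria_flags=result.criteria_flags,
            notes=result.notes + ("co_ch4_strong_biosphere_sign",),
        )
    return result
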