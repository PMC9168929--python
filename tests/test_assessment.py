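"""Tri-state criteria evaluation and the verdict lattice."""

import itertools

import pytest

from ch4context.assessment import (
    ALL_CRITERIA,
    EVIDENCE_CRITERIA,
    GATING_CRITERIA,
    CriterionStatus,
    PlanetContext,
    TriState,
    Verdict,
    assess,
    classify,
    evaluate_criteria,
)
from ch4context.fluxbalance import AtmosphereState

P, F, U = CriterionStatus.PASS, CriterionStatus.FAIL, CriterionStatus.UNKNOWN


def make_flags(default=P, **overrides):
    flags = {c: default for c in ALL_CRITERIA}
    flags.update(overrides)
    return flags


class TestEvaluateCriteria:
    def test_archean_earth_all_pass(self, archean_context):
        flags = evaluate_criteria(archean_context, implied_flux=90.0)
        assert all(v == P for v in flags.values())

    def test_high_co_ratio_fails(self, archean_context):
        atm = AtmosphereState(f_ch4=1e-3, f_co=0.1, f_co2=0.1, f_o2=0.0)
        ctx = PlanetContext(
            atmosphere=atm,
            bulk_density_terrestrial=TriState.TRUE,
            in_habitable_zone=TriState.TRUE,
            high_mean_molecular_weight_atm=TriState.TRUE,
            anoxic=TriState.TRUE,
            stellar_age=4.5e9,
            water_mass_fraction_estimate=1e-4,
        )
        flags = evaluate_criteria(ctx, implied_flux=90.0)
        assert flags["co_ch4_low"] == F  # CO/CH4 = 100

    def test_all_unknown_propagates(self):
        ctx = PlanetContext(atmosphere=AtmosphereState())
        flags = evaluate_criteria(ctx, implied_flux=None)
        assert all(v == U for v in flags.values())

    def test_threshold_edges(self, archean_context):
        # young star fails; exactly 1 Gy passes
        ctx = PlanetContext(atmosphere=archean_context.atmosphere,
                            stellar_age=5e8)
        assert evaluate_criteria(ctx)["old_star"] == F
        ctx = PlanetContext(atmosphere=archean_context.atmosphere,
                            stellar_age=1e9)
        assert evaluate_criteria(ctx)["old_star"] == P
        # 10 wt% water fails the exo-Titan discriminator
        ctx = PlanetContext(atmosphere=archean_context.atmosphere,
                            water_mass_fraction_estimate=0.10)
        assert evaluate_criteria(ctx)["low_water_fraction"] == F


class TestClassify:
    def test_all_pass_is_candidate(self):
        v = classify(make_flags())
        assert v.verdict == Verdict.CANDIDATE_BIOSIGNATURE_SEEK_CORROBORATION
        assert v.notes == ()

    def test_all_unknown_not_assessable(self):
        assert classify(make_flags(default=U)).verdict == Verdict.NOT_ASSESSABLE

    def test_gating_fail_unlikely(self):
        for gate in GATING_CRITERIA:
            v = classify(make_flags(**{gate: F}))
            assert v.verdict == Verdict.UNLIKELY_BIOGENIC

    def test_unknown_mmw_caps_verdict(self):
        """Possibly-H2-dominated atmosphere can never be a candidate."""
        v = classify(make_flags(high_mmw_atmosphere=U))
        assert v.verdict <= Verdict.POSSIBLE_ABIOTIC_FALSE_POSITIVE

    def test_evidence_fail_names_hypothesis(self):
        v = classify(make_flags(low_water_fraction=F))
        assert v.verdict == Verdict.POSSIBLE_ABIOTIC_FALSE_POSITIVE
        assert "melted_exotitan" in v.notes
        v = classify(make_flags(co_ch4_low=F))
        assert "reduced_mantle_outgassing" in v.notes
        v = classify(make_flags(flux_exceeds_abiotic=F))
        assert "serpentinization" in v.notes
        v = classify(make_flags(old_star=F))
        assert "impact_transient" in v.notes

    def test_missing_flag_rejected(self):
        flags = make_flags()
        del flags["anoxic"]
        with pytest.raises(KeyError):
            classify(flags)

    def test_pure_function(self):
        flags = make_flags(co_ch4_low=U, old_star=F)
        assert classify(flags) == classify(flags)

    def test_candidate_requires_no_fail_or_unknown(self):
        for crit in ALL_CRITERIA:
            for status in (F, U):
                v = classify(make_flags(**{crit: status}))
                assert v.verdict < Verdict.CANDIDATE_BIOSIGNATURE_SEEK_CORROBORATION


class TestLattice:
    def test_monotone_upgrades_never_weaken(self):
        """Upgrading any single criterion (fail->pass, unknown->pass) never
        lowers the verdict, over an exhaustive gating x evidence enumeration."""
        statuses = (P, F, U)
        evidence_probe = ("flux_exceeds_abiotic", "co_ch4_low")
        for gating_combo in itertools.product(statuses, repeat=len(GATING_CRITERIA)):
            for ev_combo in itertools.product(statuses, repeat=len(evidence_probe)):
                flags = make_flags()
                flags.update(zip(GATING_CRITERIA, gating_combo))
                flags.update(zip(evidence_probe, ev_combo))
                base = classify(flags).verdict
                for crit in ALL_CRITERIA:
                    if flags[crit] in (F, U):
                        upgraded = dict(flags)
                        upgraded[crit] = P
                        assert classify(upgraded).verdict >= base

    def test_every_verdict_reachable(self):
        """Brute force over all gating combinations: the lattice has no
        unreachable states."""
        statuses = (P, F, U)
        seen = set()
        for combo in itertools.product(statuses, repeat=len(GATING_CRITERIA)):
            for ev in (P, U, F):
                flags = make_flags(default=ev)
                flags.update(zip(GATING_CRITERIA, combo))
                seen.add(classify(flags).verdict)
        assert seen == set(Verdict)


class TestAssess:
    def test_archean_candidate_with_strong_sign(self, archean_context):
        v = assess(archean_context, implied_flux=90.0)
        assert v.verdict == Verdict.CANDIDATE_BIOSIGNATURE_SEEK_CORROBORATION
        # CO/CH4 = 0.1 is not strictly below the 0.1 annotation tier
        atm = AtmosphereState(f_ch4=5e-3, f_co=2.5e-4, f_co2=0.1, f_o2=0.0)
        ctx = PlanetContext(
            atmosphere=atm,
            bulk_density_terrestrial=TriState.TRUE,
            in_habitable_zone=TriState.TRUE,
            high_mean_molecular_weight_atm=TriState.TRUE,
            anoxic=TriState.TRUE,
            stellar_age=4.5e9,
            water_mass_fraction_estimate=1e-4,
        )
        v = assess(ctx, implied_flux=90.0)
        assert "co_ch4_strong_biosphere_sign" in v.notes

    def test_exotitan_water_flags_hypothesis(self, archean_context):
        ctx = PlanetContext(
            atmosphere=archean_context.atmosphere,
            bulk_density_terrestrial=TriState.TRUE,
            in_habitable_zone=TriState.TRUE,
            high_mean_molecular_weight_atm=TriState.TRUE,
            anoxic=TriState.TRUE,
            stellar_age=4.5e9,
            water_mass_fraction_estimate=0.10,
        )
        v = assess(ctx, implied_flux=90.0)
        assert v.verdict == Verdict.POSSIBLE_ABIOTIC_FALSE_POSITIVE
        assert "melted_exotitan" in v.notes
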