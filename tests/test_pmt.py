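"""The PMT/vPvM criterion rules and six-category assignment."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecotoxrank.pmt import (
    BiodegScreen,
    Category,
    CmrFlag,
    HalfLife,
    HazardEvidence,
    KocRecord,
    Mobility,
    Persistence,
    Toxicity,
    all_criterion_combinations,
    assess_mobility,
    assess_persistence,
    assess_substance,
    assess_toxicity,
    assign_category,
)


def evidence(**kwargs):
    return HazardEvidence(substance="50-00-0", **kwargs)


def hl(value, compartment="water", provenance="measured"):
    return HalfLife(value=value, compartment=compartment, provenance=provenance)


class TestPersistence:
    @pytest.mark.parametrize(
        "days,expected",
        [
            (200.0, Persistence.vP),
            (181.0, Persistence.vP),
            (180.0, Persistence.P),   # vP requires strictly > 180 d
            (100.0, Persistence.P),
            (40.0, Persistence.P),    # P is inclusive at 40 d
            (39.9, Persistence.not_P),
            (20.0, Persistence.not_P),
        ],
    )
    def test_measured_half_life_boundaries(self, days, expected):
        conclusion, trail = assess_persistence(evidence(half_lives=[hl(days)]))
        assert conclusion is expected
        assert trail

    def test_qsar_nonbiodegradable_is_potential(self):
        ev = evidence(biodeg_screens=[
            BiodegScreen(call="not_biodegradable", provenance="qsar")
        ])
        assert assess_persistence(ev)[0] is Persistence.potential_P_vP

    def test_two_screening_lines_give_plus_plus(self):
        ev = evidence(biodeg_screens=[
            BiodegScreen(call="not_biodegradable", provenance="qsar"),
            BiodegScreen(call="not_biodegradable", provenance="test"),
        ])
        assert assess_persistence(ev)[0] is Persistence.potential_P_vP_plus_plus

    def test_worst_case_across_compartments(self):
        ev = evidence(half_lives=[hl(20.0, "water"), hl(300.0, "sediment")])
        assert assess_persistence(ev)[0] is Persistence.vP

    def test_measured_overrides_screening(self):
        ev = evidence(
            half_lives=[hl(20.0)],
            biodeg_screens=[BiodegScreen(call="not_biodegradable")],
        )
        assert assess_persistence(ev)[0] is Persistence.not_P

    def test_ready_biodegradability_alone_is_not_P(self):
        ev = evidence(biodeg_screens=[BiodegScreen(call="readily")])
        assert assess_persistence(ev)[0] is Persistence.not_P

    def test_no_evidence_falls_back_to_potential_with_caveat(self):
        conclusion, trail = assess_persistence(evidence())
        assert conclusion is Persistence.potential_P_vP
        assert any("insufficient" in s for s in trail)

    @given(st.floats(min_value=1, max_value=400, allow_nan=False),
           st.floats(min_value=0, max_value=200, allow_nan=False))
    @settings(max_examples=100)
    def test_longer_half_life_never_weakens_conclusion(self, days, extra):
        order = [Persistence.not_P, Persistence.P, Persistence.vP]
        a = assess_persistence(evidence(half_lives=[hl(days)]))[0]
        b = assess_persistence(evidence(half_lives=[hl(days + extra)]))[0]
        assert order.index(b) >= order.index(a)


class TestMobility:
    @pytest.mark.parametrize(
        "log_koc,expected",
        [
            (2.5, Mobility.vM),
            (3.0, Mobility.vM),   # inclusive boundary
            (3.5, Mobility.M),
            (4.0, Mobility.M),    # inclusive boundary
            (4.5, Mobility.not_M),
        ],
    )
    def test_boundaries(self, log_koc, expected):
        ev = evidence(koc_records=[KocRecord(log_koc=log_koc, ph=7.0)])
        assert assess_mobility(ev)[0] is expected

    def test_records_outside_ph_window_excluded(self):
        ev = evidence(koc_records=[
            KocRecord(log_koc=1.0, ph=3.0),   # excluded: pH < 4
            KocRecord(log_koc=3.5, ph=7.0),
        ])
        assert assess_mobility(ev)[0] is Mobility.M

    def test_experimental_preferred_over_predicted(self):
        ev = evidence(koc_records=[
            KocRecord(log_koc=2.0, ph=7.0, provenance="predicted"),
            KocRecord(log_koc=3.5, ph=7.0, provenance="experimental"),
        ])
        assert assess_mobility(ev)[0] is Mobility.M

    def test_predicted_used_when_no_experimental(self):
        ev = evidence(koc_records=[KocRecord(log_koc=2.0, ph=7.0,
                                             provenance="predicted")])
        assert assess_mobility(ev)[0] is Mobility.vM

    def test_no_usable_records_is_not_M_with_caveat(self):
        conclusion, trail = assess_mobility(
            evidence(koc_records=[KocRecord(log_koc=1.0, ph=2.0)])
        )
        assert conclusion is Mobility.not_M
        assert any("insufficient" in s for s in trail)

    @given(st.floats(min_value=0, max_value=6, allow_nan=False),
           st.floats(min_value=0, max_value=3, allow_nan=False))
    @settings(max_examples=100)
    def test_lower_koc_never_weakens_mobility(self, koc, drop):
        order = [Mobility.not_M, Mobility.M, Mobility.vM]
        a = assess_mobility(evidence(koc_records=[KocRecord(log_koc=koc)]))[0]
        b = assess_mobility(
            evidence(koc_records=[KocRecord(log_koc=max(koc - drop, 0.0))])
        )[0]
        assert order.index(b) >= order.index(a)


class TestToxicity:
    def test_low_noec_is_T(self):
        assert assess_toxicity(evidence(noec_or_ec10=0.005))[0] is Toxicity.T

    def test_noec_exactly_at_threshold_is_not_T(self):
        ev = evidence(noec_or_ec10=0.01, cramer_class="II")
        assert assess_toxicity(ev)[0] is Toxicity.not_T

    def test_cmr_flag_is_T_without_noec(self):
        ev = evidence(cmr_flags={CmrFlag.carcinogenic})
        assert assess_toxicity(ev)[0] is Toxicity.T

    def test_stot_re_is_T(self):
        assert assess_toxicity(evidence(stot_re=True))[0] is Toxicity.T

    @pytest.mark.parametrize(
        "cramer,expected",
        [("III", Toxicity.pT), ("II", Toxicity.not_T), ("I", Toxicity.not_T)],
    )
    def test_cramer_fallback(self, cramer, expected):
        assert assess_toxicity(evidence(cramer_class=cramer))[0] is expected

    def test_no_evidence_falls_back_to_pT(self):
        conclusion, trail = assess_toxicity(evidence())
        assert conclusion is Toxicity.pT
        assert any("fallback" in s for s in trail)

    def test_adding_cmr_flag_never_weakens(self):
        for cramer in (None, "I", "II", "III"):
            base = assess_toxicity(evidence(cramer_class=cramer))[0]
            flagged = assess_toxicity(
                evidence(cramer_class=cramer, cmr_flags={CmrFlag.reproductive_toxicant})
            )[0]
            assert flagged is Toxicity.T or flagged is base


class TestCategoryAssignment:
    @pytest.mark.parametrize(
        "p,m,t,raw,expected",
        [
            (Persistence.vP, Mobility.vM, Toxicity.T, False, Category.vPvM_and_PMT),
            (Persistence.vP, Mobility.vM, Toxicity.not_T, False, Category.vPvM),
            (Persistence.P, Mobility.M, Toxicity.T, False, Category.PMT),
            (Persistence.vP, Mobility.M, Toxicity.T, False, Category.PMT),
            (Persistence.P, Mobility.M, Toxicity.not_T, False, Category.PM),
            (Persistence.potential_P_vP_plus_plus, Mobility.not_M, Toxicity.not_T,
             True, Category.vPvM),
            (Persistence.potential_P_vP_plus_plus, Mobility.not_M, Toxicity.not_T,
             False, Category.not_PMT_vPvM),
            (Persistence.not_P, Mobility.vM, Toxicity.T, False,
             Category.not_PMT_vPvM),
            (Persistence.vP, Mobility.not_M, Toxicity.T, False,
             Category.not_PMT_vPvM),
            (Persistence.potential_P_vP, Mobility.M, Toxicity.T, False,
             Category.potential_PMT_vPvM),
            # unresolved toxicity routes an otherwise-PMT substance to potential
            (Persistence.P, Mobility.vM, Toxicity.pT, False,
             Category.potential_PMT_vPvM),
        ],
    )
    def test_rule_table(self, p, m, t, raw, expected):
        assert assign_category(p, m, t, raw) is expected

    def test_total_over_all_90_combinations(self):
        combos = list(all_criterion_combinations())
        assert len(combos) == 90
        seen = set()
        for p, m, t, raw in combos:
            seen.add(assign_category(p, m, t, raw))
        assert seen == set(Category)  # all six categories are reachable

    def test_exactly_six_categories(self):
        assert len(Category) == 6


class TestWholeSubstance:
    def test_deterministic_with_full_rationale(self):
        ev = evidence(
            half_lives=[hl(200.0)],
            koc_records=[KocRecord(log_koc=2.0, ph=7.0)],
            noec_or_ec10=0.001,
        )
        a = assess_substance(ev)
        b = assess_substance(ev)
        assert a == b
        assert a.category is Category.vPvM_and_PMT
        assert a.rationale and all(isinstance(s, str) for s in a.rationale)

    def test_raw_water_route_appears_in_rationale(self):
        ev = evidence(
            biodeg_screens=[
                BiodegScreen(call="not_biodegradable", provenance="qsar"),
                BiodegScreen(call="not_biodegradable", provenance="test"),
            ],
            koc_records=[KocRecord(log_koc=5.0, ph=7.0)],
            cramer_class="I",
            detected_in_raw_water=True,
        )
        result = assess_substance(ev)
        assert result.category is Category.vPvM
        assert any("raw water" in s for s in result.rationale)

    def test_every_combination_yields_nonempty_rationale(self):
        ev = evidence()  # all-fallback evidence
        result = assess_substance(ev)
        assert result.rationale
        assert result.caveats  # fallbacks must surface as caveats
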