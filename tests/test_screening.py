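"""Screening rounds, surveillance, and colonoscopy adverse events."""

import numpy as np
import pytest
from dataclasses import replace

from crcaware.natural_history import N_STATES, HealthState as S
from crcaware.parameters import (
    AdverseEventParams,
    AgeCurve,
    ParameterError,
    ScreeningBehaviour,
    TestCharacteristics,
)
from crcaware.screening import (
    ScreeningProgramme,
    apply_screening_round,
    colonoscopy_adverse_events,
    surveillance_round,
)


@pytest.fixture
def tests_():
    return TestCharacteristics()


@pytest.fixture
def behaviour():
    return ScreeningBehaviour()


class TestScreeningRound:
    def test_zero_uptake_is_noop(self, tests_, behaviour):
        occ = np.zeros(N_STATES)
        occ[S.CLEAR] = 500.0
        occ[S.PRE_B] = 20.0
        new, to_surv, ev = apply_screening_round(occ, tests_, behaviour, 60,
                                                 uptake=0.0)
        assert np.array_equal(new, occ)
        assert to_surv == 0.0
        assert ev.colonoscopies == 0.0 and ev.gfobt_positive == 0.0

    def test_preclinical_a_detection_fraction(self, tests_, behaviour):
        """Full uptake and compliance: the screen-detected fraction is
        gFOBT CRC sensitivity x colonoscopy CRC sensitivity."""
        full = replace(behaviour, col_followup_compliance=1.0)
        occ = np.zeros(N_STATES)
        occ[S.PRE_A] = 1000.0
        new, _, ev = apply_screening_round(occ, tests_, full, 60, uptake=1.0)
        assert ev.screen_detected["A"] == pytest.approx(1000 * 0.24 * 0.98)
        assert new[S.CLIN_A] == pytest.approx(1000 * 0.24 * 0.98)

    def test_false_positive_rate_age50(self, tests_, behaviour):
        """A disease-free cohort of 1,000 at age 50 yields 10 false positives
        (specificity 0.99)."""
        occ = np.zeros(N_STATES)
        occ[S.CLEAR] = 1000.0
        _, _, ev = apply_screening_round(occ, tests_, behaviour, 50, uptake=1.0)
        assert ev.gfobt_positive == pytest.approx(10.0)

    def test_default_split_uses_per_round_uptake(self, tests_, behaviour):
        """Without an uptake override, net completion is ever x conditional
        = the unconditional per-round uptake (0.54)."""
        occ = np.zeros(N_STATES)
        occ[S.CLEAR] = 1000.0
        _, _, ev = apply_screening_round(occ, tests_, behaviour, 55)
        completed = ev.gfobt_normal + ev.gfobt_positive
        assert completed == pytest.approx(540.0)

    def test_hr_adenoma_removal_routes_to_surveillance(self, tests_, behaviour):
        full = replace(behaviour, col_followup_compliance=1.0)
        occ = np.zeros(N_STATES)
        occ[S.HR_ADENOMA] = 100.0
        new, to_surv, ev = apply_screening_round(occ, tests_, full, 62, uptake=1.0)
        expected = 100 * 0.12 * 0.98
        assert to_surv == pytest.approx(expected)
        assert new[S.CLEAR] == pytest.approx(expected)
        assert ev.polypectomies == pytest.approx(expected)

    def test_perfect_specificity_zero_sensitivity_changes_nothing(self, behaviour):
        """Only costs can arise when the test detects nothing and never
        false-alarms."""
        blind = TestCharacteristics(
            gfobt_sens={"LR": 0.0, "HR": 0.0, "CRC": 0.0},
            gfobt_spec=AgeCurve(((50, 1.0), (70, 1.0)), extrapolation="clamp"),
        )
        occ = np.zeros(N_STATES)
        occ[S.CLEAR] = 300.0
        occ[S.LR_ADENOMA] = 50.0
        occ[S.PRE_D] = 5.0
        new, to_surv, ev = apply_screening_round(occ, blind, behaviour, 64,
                                                 uptake=1.0)
        assert np.array_equal(new, occ)
        assert to_surv == 0.0
        assert ev.colonoscopies == 0.0
        assert ev.gfobt_normal == pytest.approx(355.0)  # still costed

    def test_negative_mass_rejected(self, tests_, behaviour):
        occ = np.zeros(N_STATES)
        occ[S.CLEAR] = -1.0
        with pytest.raises(ParameterError):
            apply_screening_round(occ, tests_, behaviour, 60)


class TestSurveillance:
    def test_annualised_colonoscopy_probability(self, tests_, behaviour):
        prog = ScreeningProgramme()
        occ = np.zeros(N_STATES)
        occ[S.CLEAR] = 90.0
        new, ev = surveillance_round(occ, tests_, behaviour, prog)
        assert ev.colonoscopies == pytest.approx(90 * 0.83 / 3)
        assert np.array_equal(new, occ)  # nothing to find

    def test_detects_preclinical_cancer(self, tests_, behaviour):
        prog = ScreeningProgramme()
        occ = np.zeros(N_STATES)
        occ[S.PRE_C] = 30.0
        new, ev = surveillance_round(occ, tests_, behaviour, prog)
        expected = 30 * (0.83 / 3) * 0.98
        assert ev.screen_detected["C"] == pytest.approx(expected)
        assert new[S.CLIN_C] == pytest.approx(expected)


class TestProgramme:
    def test_biennial_invitations(self):
        prog = ScreeningProgramme(start_age=60, stop_age=69, interval_years=2)
        invited = [a for a in range(55, 75) if prog.invites_at(a)]
        assert invited == [60, 62, 64, 66, 68]

    def test_disabled_programme_never_invites(self):
        prog = ScreeningProgramme(enabled=False)
        assert not any(prog.invites_at(a) for a in range(30, 100))


class TestAdverseEvents:
    def test_zero_counts(self):
        res = colonoscopy_adverse_events(0, 0, AdverseEventParams())
        assert res == (0.0, 0.0, 0.0, 0.0)

    def test_referral_scenario_bleeds(self):
        """17,519 colonoscopies without polypectomy: ~52.6 bleed admissions
        costing ~GBP 14.6K (printed rounded to 50 cases / GBP 14K)."""
        res = colonoscopy_adverse_events(17_519, 0, AdverseEventParams())
        assert res.bleeds == pytest.approx(52.557)
        assert res.total_cost == pytest.approx(52.557 * 278, rel=1e-9)
        assert res.perforations == 0.0

    def test_polypectomy_perforations(self):
        res = colonoscopy_adverse_events(1000, 1000, AdverseEventParams())
        assert res.perforations == pytest.approx(3.0)
        assert res.perforation_deaths == pytest.approx(0.156)

    def test_polypectomies_cannot_exceed_colonoscopies(self):
        with pytest.raises(ParameterError):
            colonoscopy_adverse_events(10, 11, AdverseEventParams())


class TestScreeningInPopulation:
    def test_diagnosis_route_partition(self, params, survival,
                                       single_cohort_demography):
        """Screen-detected plus symptomatic inflows account exactly for the
        clinical-state balance every cycle (single-cohort accounting)."""
        from crcaware.natural_history import (
            CLINICAL, build_transition_matrix, run_population,
        )

        trace = run_population(
            single_cohort_demography, params.natural_history, survival,
            params.tests, params.behaviour, ScreeningProgramme(),
        )
        c = 40 - 30
        clin = [int(CLINICAL[s]) for s in "ABCD"]
        for t in range(trace.n_cycles):
            age = 40 + t
            if age >= 100:
                break
            M = build_transition_matrix(
                age, params.natural_history, survival, single_cohort_demography
            )
            post_screen = trace.occupancy[t, c, clin] + trace.screen_diag[t, c]
            stay = np.array([M[i, i] for i in clin])
            expected_next = post_screen * stay + trace.sympt_diag[t, c]
            assert np.allclose(trace.occupancy[t + 1, c, clin], expected_next,
                               atol=1e-12)

    def test_campaign_reduces_screen_detected(self, base_eval, campaign_eval):
        """Earlier symptomatic presentation pre-empts screening detection."""
        d = (campaign_eval[0].cumulative_screen_detected_by_stage()
             - base_eval[0].cumulative_screen_detected_by_stage())
        assert np.all(d < 0)
        assert d.sum() < 0
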