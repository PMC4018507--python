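"""The state-transition engine: matrices, cohort advancement, population runs."""

import numpy as np
import pytest

from crcaware.experiments import ModelInputs, _evaluate
from crcaware.natural_history import (
    ALIVE_STATES,
    CLINICAL,
    N_STATES,
    PRECLINICAL,
    HealthState,
    advance_cohort,
    build_transition_matrix,
    campaign_adjusted_presentation,
    run_population,
)
from crcaware.parameters import CampaignScenario, ParameterError
from crcaware.screening import ScreeningProgramme
from crcaware.synthetic_data import Demography, make_demography_fixture


def zero_mortality_demography():
    ages = np.arange(30, 101)
    return Demography(
        ages=ages,
        population=np.ones_like(ages, dtype=float),
        all_cause_mortality=np.zeros_like(ages, dtype=float),
    )


class TestCampaignAdjustedPresentation:
    def test_zero_multiplier_is_identity(self):
        assert campaign_adjusted_presentation(0.74, 0.0, 6) == 0.74

    def test_one_month_ten_percent(self):
        # hazard -ln(0.26) scaled by 1 + 0.1/12
        exact = 1 - 0.26 ** (1 + 0.10 / 12)
        v = campaign_adjusted_presentation(0.74, 0.10, 1)
        assert v == pytest.approx(exact, abs=1e-12)
        assert v == pytest.approx(0.7429, abs=5e-5)

    def test_full_year_scaling(self):
        assert campaign_adjusted_presentation(0.37, 0.10, 12) == pytest.approx(
            1 - 0.63**1.1, abs=1e-12
        )

    def test_certain_presentation_rejected(self):
        with pytest.raises(ParameterError):
            campaign_adjusted_presentation(1.0, 0.1, 1)

    def test_small_p_excess_approximates_md_over_12(self):
        p = 0.001
        v = campaign_adjusted_presentation(p, 0.12, 6)
        assert (v - p) / p == pytest.approx(0.12 * 6 / 12, rel=0.01)


class TestTransitionMatrix:
    @pytest.mark.parametrize("age", [30, 45, 60, 75, 99])
    @pytest.mark.parametrize("mult", [None, {"A": 0.1, "B": 0.1, "C": 0.1, "D": 0.1}])
    def test_rows_sum_to_one(self, inputs, survival, age, mult):
        M = build_transition_matrix(
            age, inputs.params.natural_history, survival, inputs.demography,
            presentation_multiplier_by_stage=mult,
            duration_months=1 if mult else 0,
        )
        assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((M >= 0) & (M <= 1))

    def test_clear_row_offdiagonal_mass_age30(self, params, null_survival):
        """With no background mortality, the clear-epithelium exits at age 30
        are the printed adenoma-onset plus de-novo carcinoma probabilities."""
        M = build_transition_matrix(
            30, params.natural_history, null_survival, zero_mortality_demography()
        )
        off = 1.0 - M[HealthState.CLEAR, HealthState.CLEAR]
        assert off == pytest.approx(0.021 + 0.00004, abs=1e-5)
        assert M[HealthState.CLEAR, HealthState.LR_ADENOMA] > 0
        assert M[HealthState.CLEAR, HealthState.PRE_A] > 0

    def test_single_exit_probability_is_exact(self, params, null_survival):
        """Hazard composition with one competing flow returns it unchanged."""
        M = build_transition_matrix(
            50, params.natural_history, null_survival, zero_mortality_demography()
        )
        # preclinical D has only symptomatic presentation left
        assert M[HealthState.PRE_D, HealthState.CLIN_D] == pytest.approx(
            0.74, abs=1e-15
        )

    def test_null_survival_no_crc_death(self, params, null_survival, inputs):
        M = build_transition_matrix(
            60, params.natural_history, null_survival, inputs.demography
        )
        for s in "ABCD":
            assert M[CLINICAL[s], HealthState.DEAD_CRC] == 0.0

    def test_absorbing_states(self, inputs, survival):
        M = build_transition_matrix(
            70, inputs.params.natural_history, survival, inputs.demography
        )
        for s in (HealthState.DEAD_CRC, HealthState.DEAD_OTHER,
                  HealthState.DEAD_OTHER_UNDIAG_CRC):
            assert M[s, s] == 1.0
            assert M[s].sum() == 1.0


class TestAdvanceCohort:
    def test_identity_matrix_preserves_occupancy(self):
        occ = np.random.default_rng(0).random((3, N_STATES))
        assert np.array_equal(advance_cohort(occ, np.eye(N_STATES)), occ)

    def test_toy_chain_matches_hand_product(self):
        """Two cycles of a 3-state chain equal the explicit matrix product."""
        M = np.array([[0.7, 0.2, 0.1], [0.0, 0.6, 0.4], [0.0, 0.0, 1.0]])
        v = np.array([1.0, 0.0, 0.0])
        out = advance_cohort(advance_cohort(v, M), M)
        assert np.allclose(out, v @ M @ M, atol=1e-15)

    def test_mass_conserved(self):
        rng = np.random.default_rng(1)
        M = rng.random((4, 4))
        M /= M.sum(axis=1, keepdims=True)
        v = rng.random(4)
        assert advance_cohort(v, M).sum() == pytest.approx(v.sum(), rel=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            advance_cohort(np.ones(3), np.eye(4))


class TestRunPopulation:
    def test_null_campaign_equals_no_campaign(self, inputs):
        null = CampaignScenario(
            stage_multipliers={s: 0.0 for s in "ABCD"}, duration_months=1
        )
        t0 = run_population(
            inputs.demography, inputs.params.natural_history, inputs.survival,
            inputs.params.tests, inputs.params.behaviour, inputs.programme,
            campaign=None,
        )
        t1 = run_population(
            inputs.demography, inputs.params.natural_history, inputs.survival,
            inputs.params.tests, inputs.params.behaviour, inputs.programme,
            campaign=null,
        )
        assert np.array_equal(t0.occupancy, t1.occupancy)
        assert np.array_equal(t0.sympt_diag, t1.sympt_diag)

    def test_mass_conservation(self, base_eval):
        """Per cohort, total occupancy is constant over all cycles."""
        trace = base_eval[0]
        mass = trace.cohort_mass()
        assert np.allclose(mass, mass[0][None, :], rtol=1e-9)

    def test_engine_matches_dense_matrix_product_oracle(self, params, survival):
        """Without screening, cohort evolution equals explicit products of the
        age-specific matrices (<=5 cohorts, 10 cycles, 1e-12)."""
        demo = make_demography_fixture(1000, "uniform")
        pop = np.zeros_like(demo.population)
        for age in (40, 52, 61, 75, 88):
            pop[age - 30] = 7.0
        demo = Demography(ages=demo.ages, population=pop,
                          all_cause_mortality=demo.all_cause_mortality)
        trace = run_population(
            demo, params.natural_history, survival,
            programme=ScreeningProgramme(enabled=False),
        )
        mats = {
            a: build_transition_matrix(a, params.natural_history, survival, demo)
            for a in range(30, 100)
        }
        for age in (40, 52, 61, 75, 88):
            c = age - 30
            v = trace.occupancy[0, c]
            for t in range(10):
                v = v @ mats[age + t]
                assert np.allclose(trace.occupancy[t + 1, c], v, atol=1e-12)

    def test_single_person_cohort_matches_oracle(
        self, params, survival, single_cohort_demography
    ):
        trace = run_population(
            single_cohort_demography, params.natural_history, survival,
            programme=ScreeningProgramme(enabled=False),
        )
        c = 40 - 30
        M = build_transition_matrix(
            40, params.natural_history, survival, single_cohort_demography
        )
        assert np.allclose(trace.occupancy[1, c], trace.occupancy[0, c] @ M,
                           atol=1e-14)
        assert trace.occupancy[0, c].sum() == pytest.approx(1.0)

    def test_zero_crc_mortality_campaign_leaves_life_years_unchanged(
        self, params, null_survival
    ):
        """With no excess cancer mortality the campaign cannot change survival,
        so total life-years are identical with and without it."""
        from crcaware.economics import accumulate_qalys
        from crcaware.synthetic_data import make_survival_fixture

        demo = make_demography_fixture(1e5, "uniform")
        kw = dict(
            demography=demo, nh=params.natural_history, survival=null_survival,
            tests=params.tests, behaviour=params.behaviour,
            programme=ScreeningProgramme(enabled=False),
        )
        t0 = run_population(**kw)
        t1 = run_population(**kw, campaign=CampaignScenario())
        # agreement up to the one-transition-per-cycle discretisation (~1e-8)
        ly0 = accumulate_qalys(t0, params.economics)[0]
        ly1 = accumulate_qalys(t1, params.economics)[0]
        assert ly1 == pytest.approx(ly0, rel=1e-6)

    def test_cycle_one_presentation_increase(self, base_eval, campaign_eval):
        """Cycle-1 symptomatic diagnoses rise per stage by the exact
        hazard-scaling factor; for small-p stages this is within 10% of
        1 + m*d/12."""
        t0, t1 = base_eval[0], campaign_eval[0]
        x = 0.10 * 1 / 12
        pres = {"A": 0.04, "B": 0.18, "C": 0.37, "D": 0.74}
        for k, s in enumerate("ABCD"):
            ratio = t1.sympt_diag[0, :, k].sum() / t0.sympt_diag[0, :, k].sum()
            # closed form ignores the (small) competing background mortality
            exact = (1 - (1 - pres[s]) ** (1 + x)) / pres[s]
            assert ratio == pytest.approx(exact, rel=1e-3)
        ratio_a = t1.sympt_diag[0, :, 0].sum() / t0.sympt_diag[0, :, 0].sum()
        assert 1 + 0.9 * x < ratio_a < 1 + 1.1 * x

    def test_stage_shift_direction(self, base_eval, campaign_eval):
        """Base-case campaign: more lifetime symptomatic diagnoses in Dukes'
        A-C, fewer in D."""
        d = (campaign_eval[0].cumulative_symptomatic_by_stage()
             - base_eval[0].cumulative_symptomatic_by_stage())
        assert d[0] > 0 and d[1] > 0 and d[2] > 0 and d[3] < 0

    def test_fewer_crc_deaths_under_campaign(self, base_eval, campaign_eval):
        assert campaign_eval[0].total_crc_deaths() < base_eval[0].total_crc_deaths()

    def test_death_partition(self, base_eval):
        """All mass lost from alive states ends in exactly one death state."""
        trace = base_eval[0]
        alive = [int(s) for s in ALIVE_STATES]
        start_alive = trace.occupancy[0][:, alive].sum()
        end_alive = trace.occupancy[-1][:, alive].sum()
        deaths = (trace.crc_deaths.sum() + trace.other_deaths.sum()
                  + trace.deaths_undiagnosed_crc.sum())
        assert deaths == pytest.approx(start_alive - end_alive, rel=1e-9)
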