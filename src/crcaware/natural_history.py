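"""Discrete-time state-transition engine for colorectal cancer natural history.

The disease model follows the adenoma-carcinoma sequence: clear epithelium may
develop low-risk adenomas, which may become high-risk adenomas and then
preclinical (undiagnosed) cancer progressing through Dukes' stages A-D. A small
direct route from clear epithelium to preclinical Dukes' A captures de novo
carcinomas. Preclinical cancer is diagnosed through symptomatic or chance
presentation at a stage-dependent annual probability, or through screening
(overlaid by :mod:`crcaware.screening`). Diagnosed (clinical) cancer carries a
stage-dependent annual cancer-death probability; everyone is exposed to
all-cause background mortality, with deaths of people carrying undiagnosed
cancer tracked in a separate absorbing state.

Cycles are annual. An awareness campaign acting for d months of the first
model year is embedded analytically: the annual presentation probability p is
converted to a constant hazard r = -ln(1-p), the hazard is scaled by (1+m)
for d of the 12 months, and the adjusted annual probability is
1 - exp(-r(1 + m*d/12)). Competing transitions out of a state are composed on
the log-survival (hazard) scale, which makes every row of the one-cycle
transition matrix sum to one by construction and is order-independent.

The population is a deterministic multi-cohort model: every current single
year of age 30-100 is a cohort followed to age 100 or death. Prevalent disease
in the current population is constructed by a burn-in — a single cohort run
from age 30 under no-campaign dynamics whose alive-state distribution at each
age seeds the corresponding starting cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np

from .parameters import (
    STAGES,
    NaturalHistoryParams,
    ParameterError,
    ScreeningBehaviour,
    TestCharacteristics,
    CampaignScenario,
)
from .synthetic_data import AGE_MAX, AGE_MIN, Demography, SurvivalFixture

__all__ = [
    "HealthState",
    "N_STATES",
    "ALIVE_STATES",
    "UNDIAGNOSED_STATES",
    "PRECLINICAL",
    "CLINICAL",
    "CohortTrace",
    "campaign_adjusted_presentation",
    "build_transition_matrix",
    "advance_cohort",
    "run_population",
]


class HealthState(IntEnum):
    """The 14 health states. The last three are absorbing."""

    CLEAR = 0
    LR_ADENOMA = 1
    HR_ADENOMA = 2
    PRE_A = 3
    PRE_B = 4
    PRE_C = 5
    PRE_D = 6
    CLIN_A = 7
    CLIN_B = 8
    CLIN_C = 9
    CLIN_D = 10
    DEAD_CRC = 11
    DEAD_OTHER = 12
    DEAD_OTHER_UNDIAG_CRC = 13


N_STATES = len(HealthState)

#: Preclinical and clinical state index per Dukes' stage.
PRECLINICAL: dict[str, HealthState] = {
    "A": HealthState.PRE_A,
    "B": HealthState.PRE_B,
    "C": HealthState.PRE_C,
    "D": HealthState.PRE_D,
}
CLINICAL: dict[str, HealthState] = {
    "A": HealthState.CLIN_A,
    "B": HealthState.CLIN_B,
    "C": HealthState.CLIN_C,
    "D": HealthState.CLIN_D,
}
ABSORBING = (
    HealthState.DEAD_CRC,
    HealthState.DEAD_OTHER,
    HealthState.DEAD_OTHER_UNDIAG_CRC,
)
ALIVE_STATES = tuple(s for s in HealthState if s not in ABSORBING)
#: Alive states in which cancer, if present, is not yet diagnosed.
UNDIAGNOSED_STATES = (
    HealthState.CLEAR,
    HealthState.LR_ADENOMA,
    HealthState.HR_ADENOMA,
    HealthState.PRE_A,
    HealthState.PRE_B,
    HealthState.PRE_C,
    HealthState.PRE_D,
)


def campaign_adjusted_presentation(
    p_annual: float, multiplier: float, duration_months: float
) -> float:
    """Annual presentation probability under a d-month hazard increase.

    The constant hazard r = -ln(1 - p) is scaled by (1 + multiplier) for
    ``duration_months`` of the year, giving 1 - exp(-r(1 + m*d/12)). For small
    p the first-year excess incidence is approximately m*d/12.
    """
    if not (0.0 <= p_annual <= 1.0):
        raise ParameterError(f"p_annual = {p_annual} not a probability")
    if p_annual == 1.0:
        raise ParameterError("annual probability 1 implies infinite hazard")
    if multiplier < 0:
        raise ParameterError("multiplier must be >= 0")
    if not (0 <= duration_months <= 12):
        raise ParameterError("duration_months must lie in [0, 12]")
    if multiplier == 0.0 or duration_months == 0:
        return p_annual
    r = -math.log1p(-p_annual)
    return -math.expm1(-r * (1.0 + multiplier * duration_months / 12.0))


def _compose_row(dests: Mapping[int, float]) -> tuple[float, dict[int, float]]:
    """Compose competing annual probabilities on the hazard scale.

    Returns (stay probability, destination probabilities). Each annual
    probability p_i becomes hazard h_i = -ln(1-p_i); the one-cycle exit
    probability 1-exp(-sum h) is split proportionally to the hazards.
    """
    hazards = {}
    for j, p in dests.items():
        if p < 0 or p > 1:
            raise ParameterError(f"transition probability {p} outside [0, 1]")
        if p == 1.0:
            raise ParameterError("competing transition with probability 1")
        if p > 0:
            hazards[j] = -math.log1p(-p)
    total = sum(hazards.values())
    if total == 0.0:
        return 1.0, {}
    exit_prob = -math.expm1(-total)
    return 1.0 - exit_prob, {j: exit_prob * h / total for j, h in hazards.items()}


def build_transition_matrix(
    age: float,
    nh: NaturalHistoryParams,
    survival: SurvivalFixture,
    demography: Demography,
    presentation_multiplier_by_stage: Mapping[str, float] | None = None,
    duration_months: float = 0,
) -> np.ndarray:
    """One-cycle transition matrix at a given age.

    Combines adenoma-pathway onset/progression (age-interpolated), the direct
    clear-epithelium -> Dukes' A route, preclinical stage progression,
    stage-specific symptomatic presentation (campaign-adjusted when multipliers
    are supplied), background mortality from the demography (routing
    preclinical occupants to the dead-with-undiagnosed-CRC state), and
    cancer mortality from the survival fixture in clinical states.
    """
    S = HealthState
    q_other = demography.mortality_at(age)
    mult = presentation_multiplier_by_stage or {}

    def pres(stage: str) -> float:
        return campaign_adjusted_presentation(
            nh.presentation[stage], mult.get(stage, 0.0), duration_months
        )

    rows: dict[int, dict[int, float]] = {
        S.CLEAR: {
            S.LR_ADENOMA: nh.adenoma_onset(age),
            S.PRE_A: nh.normal_to_crcA,
            S.DEAD_OTHER: q_other,
        },
        S.LR_ADENOMA: {S.HR_ADENOMA: nh.lr_to_hr(age), S.DEAD_OTHER: q_other},
        S.HR_ADENOMA: {S.PRE_A: nh.hr_to_crcA(age), S.DEAD_OTHER: q_other},
        S.PRE_A: {
            S.PRE_B: nh.stage_progression["A"],
            S.CLIN_A: pres("A"),
            S.DEAD_OTHER_UNDIAG_CRC: q_other,
        },
        S.PRE_B: {
            S.PRE_C: nh.stage_progression["B"],
            S.CLIN_B: pres("B"),
            S.DEAD_OTHER_UNDIAG_CRC: q_other,
        },
        S.PRE_C: {
            S.PRE_D: nh.stage_progression["C"],
            S.CLIN_C: pres("C"),
            S.DEAD_OTHER_UNDIAG_CRC: q_other,
        },
        S.PRE_D: {S.CLIN_D: pres("D"), S.DEAD_OTHER_UNDIAG_CRC: q_other},
    }
    for stage in STAGES:
        rows[CLINICAL[stage]] = {
            S.DEAD_CRC: survival.constant_annual_probability(stage),
            S.DEAD_OTHER: q_other,
        }

    M = np.zeros((N_STATES, N_STATES))
    for i in range(N_STATES):
        if i in (int(s) for s in ABSORBING):
            M[i, i] = 1.0
            continue
        stay, moves = _compose_row(rows[HealthState(i)])
        M[i, i] = stay
        for j, p in moves.items():
            M[i, j] = p
    if np.any(M < 0) or np.any(M > 1):
        raise ParameterError("assembled transition matrix has entries outside [0, 1]")
    return M


def advance_cohort(occupancy: np.ndarray, matrices: np.ndarray) -> np.ndarray:
    """Advance occupancy one cycle.

    ``occupancy`` has shape (..., n_states) with an optional leading cohort
    axis; ``matrices`` is either a single (S, S) matrix applied to all rows or
    a per-cohort stack (n_cohorts, S, S) aligned with the first axis.
    """
    occupancy = np.asarray(occupancy, dtype=float)
    matrices = np.asarray(matrices, dtype=float)
    if matrices.ndim == 2:
        if occupancy.shape[-1] != matrices.shape[0]:
            raise ValueError("state-dimension mismatch")
        return occupancy @ matrices
    if occupancy.shape[0] != matrices.shape[0]:
        raise ValueError("cohort-dimension mismatch")
    return np.einsum("c...i,cij->c...j", occupancy, matrices)


@dataclass
class CohortTrace:
    """State occupancy over time plus per-cycle event tallies.

    ``occupancy[t, c, s]`` is persons of cohort c in state s at the start of
    cycle t (cycle 0 is the campaign year); the final snapshot is terminal.
    Event arrays are flows during cycle t. ``screening_counts`` holds
    population-level per-cycle screening activity.
    """

    start_ages: np.ndarray
    occupancy: np.ndarray                      # (T+1, n_cohorts, N_STATES)
    active: np.ndarray                         # (T, n_cohorts) bool
    sympt_diag: np.ndarray                     # (T, n_cohorts, 4)
    screen_diag: np.ndarray                    # (T, n_cohorts, 4)
    crc_deaths: np.ndarray                     # (T, n_cohorts)
    other_deaths: np.ndarray                   # (T, n_cohorts)
    deaths_undiagnosed_crc: np.ndarray         # (T, n_cohorts)
    screening_counts: dict[str, np.ndarray]    # each (T,)

    @property
    def n_cycles(self) -> int:
        return self.active.shape[0]

    @property
    def n_cohorts(self) -> int:
        return self.start_ages.size

    def cohort_mass(self) -> np.ndarray:
        """Total mass per cohort per snapshot (should be constant)."""
        return self.occupancy.sum(axis=2)

    def total_by_state(self, t: int) -> np.ndarray:
        return self.occupancy[t].sum(axis=0)

    def cumulative_symptomatic_by_stage(self) -> np.ndarray:
        return self.sympt_diag.sum(axis=(0, 1))

    def cumulative_screen_detected_by_stage(self) -> np.ndarray:
        return self.screen_diag.sum(axis=(0, 1))

    def total_crc_deaths(self) -> float:
        return float(self.crc_deaths.sum())

    def total_deaths_undiagnosed(self) -> float:
        return float(self.deaths_undiagnosed_crc.sum())

    def to_frame(self):
        """Tidy occupancy export: cycle, cohort start age, state, persons."""
        import pandas as pd

        T1, C, S = self.occupancy.shape
        idx = pd.MultiIndex.from_product(
            [range(T1), self.start_ages, [s.name for s in HealthState]],
            names=["cycle", "cohort_start_age", "state"],
        )
        return pd.DataFrame(
            {"persons": self.occupancy.reshape(-1)}, index=idx
        ).reset_index()

    def events_frame(self):
        """Tidy per-cycle event export."""
        import pandas as pd

        T = self.n_cycles
        data = {
            "cycle": np.arange(T),
            "crc_deaths": self.crc_deaths.sum(axis=1),
            "other_deaths": self.other_deaths.sum(axis=1),
            "deaths_undiagnosed_crc": self.deaths_undiagnosed_crc.sum(axis=1),
        }
        for k, s in enumerate(STAGES):
            data[f"symptomatic_{s}"] = self.sympt_diag[:, :, k].sum(axis=1)
            data[f"screen_detected_{s}"] = self.screen_diag[:, :, k].sum(axis=1)
        for key, arr in self.screening_counts.items():
            data[key] = arr
        return pd.DataFrame(data)


_COUNT_KEYS = (
    "invitations",
    "gfobt_normal",
    "gfobt_positive",
    "gfobt_noncompliers",
    "colonoscopies",
    "surveillance_colonoscopies",
    "polypectomies",
)


def _initial_distributions(
    base_matrices: dict[int, np.ndarray],
    behaviour: ScreeningBehaviour | None,
    tests: TestCharacteristics | None,
    programme,
) -> dict[int, np.ndarray]:
    """Alive-state distribution by age from a burn-in cohort run.

    Runs one cohort from age 30 under no-campaign dynamics (screening
    included when a programme is supplied) and returns, for each age, the
    normalised alive-state occupancy split by (behaviour group, surveillance
    flag, state). Groups are 0 = never-attenders, 1 = ever-attenders.
    """
    from .screening import apply_screening_round, surveillance_round

    ever = behaviour.ever_participation if behaviour is not None else 0.0
    v = np.zeros((2, 2, N_STATES))
    v[0, 0, HealthState.CLEAR] = 1.0 - ever
    v[1, 0, HealthState.CLEAR] = ever

    dists: dict[int, np.ndarray] = {}
    for age in range(AGE_MIN, AGE_MAX + 1):
        alive = v.copy()
        alive[:, :, [int(s) for s in ABSORBING]] = 0.0
        total = alive.sum()
        dists[age] = alive / total if total > 0 else alive
        if age >= AGE_MAX:
            break
        if programme is not None and programme.enabled:
            if programme.invites_at(age):
                occ = v[1, 0].copy()
                occ, to_surv, _ = apply_screening_round(
                    occ, tests, behaviour, age,
                    uptake=behaviour.conditional_uptake,
                )
                v[1, 0] = occ
                v[1, 0, HealthState.CLEAR] -= to_surv
                v[1, 1, HealthState.CLEAR] += to_surv
            for g in (0, 1):
                occ, _ = surveillance_round(v[g, 1], tests, behaviour, programme)
                v[g, 1] = occ
        v = v @ base_matrices[age]
    return dists


def run_population(
    demography: Demography,
    nh: NaturalHistoryParams,
    survival: SurvivalFixture,
    tests: TestCharacteristics | None = None,
    behaviour: ScreeningBehaviour | None = None,
    programme=None,
    campaign: CampaignScenario | None = None,
    stage_restricted_to: Sequence[str] | None = None,
) -> CohortTrace:
    """Simulate every current age cohort to age 100 or death.

    The campaign (if any) adjusts presentation probabilities during cycle 0
    only. ``stage_restricted_to`` limits the campaign multipliers to a stage
    subset (the scenario where only late-stage presentation responds). A
    ``campaign`` of ``None`` and a null scenario produce identical traces.
    """
    base = {
        age: build_transition_matrix(age, nh, survival, demography)
        for age in range(AGE_MIN, AGE_MAX)
    }
    if campaign is not None and not campaign.is_null:
        multipliers = dict(campaign.stage_multipliers)
        if stage_restricted_to is not None:
            multipliers = {
                s: (multipliers[s] if s in set(stage_restricted_to) else 0.0)
                for s in STAGES
            }
        cyc0 = {
            age: build_transition_matrix(
                age, nh, survival, demography,
                presentation_multiplier_by_stage=multipliers,
                duration_months=campaign.duration_months,
            )
            for age in range(AGE_MIN, AGE_MAX)
        }
    else:
        cyc0 = base

    screening_on = programme is not None and getattr(programme, "enabled", False)
    if screening_on and (tests is None or behaviour is None):
        raise ParameterError("screening programme requires tests and behaviour")

    dists = _initial_distributions(
        base, behaviour, tests, programme if screening_on else None
    )

    start_ages = np.arange(AGE_MIN, AGE_MAX + 1)
    n_cohorts = start_ages.size
    T = AGE_MAX - AGE_MIN  # cycles until the youngest cohort reaches 100

    # occupancy by cohort, behaviour group, surveillance flag, state
    occ = np.zeros((n_cohorts, 2, 2, N_STATES))
    for c, a0 in enumerate(start_ages):
        occ[c] = demography.population_at(a0) * dists[a0]

    trace = CohortTrace(
        start_ages=start_ages,
        occupancy=np.zeros((T + 1, n_cohorts, N_STATES)),
        active=np.zeros((T, n_cohorts), dtype=bool),
        sympt_diag=np.zeros((T, n_cohorts, len(STAGES))),
        screen_diag=np.zeros((T, n_cohorts, len(STAGES))),
        crc_deaths=np.zeros((T, n_cohorts)),
        other_deaths=np.zeros((T, n_cohorts)),
        deaths_undiagnosed_crc=np.zeros((T, n_cohorts)),
        screening_counts={k: np.zeros(T) for k in _COUNT_KEYS},
    )

    from .screening import apply_screening_round

    S = HealthState
    undiag = [int(s) for s in UNDIAGNOSED_STATES]
    for t in range(T + 1):
        trace.occupancy[t] = occ.sum(axis=(1, 2))
        if t == T:
            break
        ages = start_ages + t
        active = ages < AGE_MAX
        trace.active[t] = active
        matrices = cyc0 if t == 0 else base

        if screening_on:
            for c in np.flatnonzero(active):
                age = int(ages[c])
                if programme.invites_at(age):
                    eligible = occ[c, :, 0][:, undiag].sum()
                    trace.screening_counts["invitations"][t] += eligible
                    vec = occ[c, 1, 0].copy()
                    new, to_surv, ev = apply_screening_round(
                        vec, tests, behaviour, age,
                        uptake=behaviour.conditional_uptake,
                    )
                    occ[c, 1, 0] = new
                    occ[c, 1, 0, S.CLEAR] -= to_surv
                    occ[c, 1, 1, S.CLEAR] += to_surv
                    for k, stage in enumerate(STAGES):
                        trace.screen_diag[t, c, k] += ev.screen_detected[stage]
                    trace.screening_counts["gfobt_normal"][t] += ev.gfobt_normal
                    trace.screening_counts["gfobt_positive"][t] += ev.gfobt_positive
                    trace.screening_counts["gfobt_noncompliers"][t] += (
                        eligible - ev.gfobt_normal - ev.gfobt_positive
                    )
                    trace.screening_counts["colonoscopies"][t] += ev.colonoscopies
                    trace.screening_counts["polypectomies"][t] += ev.polypectomies
            # surveillance, vectorised over cohorts and behaviour groups
            act = np.flatnonzero(active)
            surv = occ[act][:, :, 1, :]  # (n_active, group, state)
            if surv[:, :, undiag].sum() > 0:
                p_col = (
                    behaviour.col_surveillance_compliance
                    / programme.surveillance_interval_years
                )
                trace.screening_counts["surveillance_colonoscopies"][t] += (
                    surv[:, :, undiag].sum() * p_col
                )
                for state, sens in (
                    (S.LR_ADENOMA, tests.col_sens["LR"]),
                    (S.HR_ADENOMA, tests.col_sens["HR"]),
                ):
                    removed = surv[:, :, state] * p_col * sens
                    surv[:, :, state] -= removed
                    surv[:, :, S.CLEAR] += removed
                    trace.screening_counts["polypectomies"][t] += removed.sum()
                for k, stage in enumerate(STAGES):
                    i, j = int(PRECLINICAL[stage]), int(CLINICAL[stage])
                    found = surv[:, :, i] * p_col * tests.col_sens["CRC"]
                    surv[:, :, i] -= found
                    surv[:, :, j] += found
                    trace.screen_diag[t, act, k] += found.sum(axis=1)
                occ[act, :, 1, :] = surv

        idx = np.flatnonzero(active)
        Mstack = np.stack([matrices[int(ages[c])] for c in idx])
        sub = occ[idx]
        # flow tallies from the pre-transition occupancy
        for k, stage in enumerate(STAGES):
            i, j = int(PRECLINICAL[stage]), int(CLINICAL[stage])
            trace.sympt_diag[t, idx, k] = sub[:, :, :, i].sum(axis=(1, 2)) * Mstack[:, i, j]
        clin = np.array([int(CLINICAL[s]) for s in STAGES])
        trace.crc_deaths[t, idx] = np.einsum(
            "cgsk,ck->c", sub[:, :, :, clin], Mstack[:, clin, S.DEAD_CRC]
        )
        alive_idx = np.array([int(s) for s in ALIVE_STATES])
        trace.other_deaths[t, idx] = np.einsum(
            "cgsk,ck->c", sub[:, :, :, alive_idx], Mstack[:, alive_idx, S.DEAD_OTHER]
        )
        pre = np.array([int(PRECLINICAL[s]) for s in STAGES])
        trace.deaths_undiagnosed_crc[t, idx] = np.einsum(
            "cgsk,ck->c",
            sub[:, :, :, pre],
            Mstack[:, pre, S.DEAD_OTHER_UNDIAG_CRC],
        )
        occ[idx] = np.einsum("cgsi,cij->cgsj", sub, Mstack)

    return trace
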