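"""Biennial gFOBT screening overlay with colonoscopy follow-up and surveillance.

A screening round splits the eligible population into never-participants
(share 1 - ever_participation) and ever-participants, who complete the test
with the conditional per-round uptake. Positives (true, by lesion-class
sensitivity; false, by 1 - age-interpolated specificity) proceed to
colonoscopy with the follow-up compliance. Colonoscopy finds lesions with its
own sensitivity: adenomas are removed by polypectomy (the person returns to
clear epithelium, high-risk carriers enter surveillance), preclinical cancer
becomes screen-detected clinical cancer of the same stage. Surveillance is a
periodic colonoscopy for previously detected high-risk-adenoma patients,
approximated as an annual colonoscopy probability of compliance / interval.

Adverse events (perforation, with a small death risk, only when polypectomy is
performed; bleeding admissions) are carried as expected counts and costs; they
do not feed back into the state engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .parameters import (
    STAGES,
    AdverseEventParams,
    ParameterError,
    ScreeningBehaviour,
    TestCharacteristics,
    interpolate_age_curve,
)

__all__ = [
    "ScreeningProgramme",
    "ScreeningEventCounts",
    "AdverseEventResult",
    "apply_screening_round",
    "surveillance_round",
    "colonoscopy_adverse_events",
]


@dataclass(frozen=True)
class ScreeningProgramme:
    """Programme settings: invitation ages/interval and surveillance schedule."""

    start_age: int = 60
    stop_age: int = 69
    interval_years: int = 2
    surveillance_interval_years: int = 3
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.start_age > self.stop_age:
            raise ParameterError("screening start_age must be <= stop_age")
        if self.interval_years < 1 or self.surveillance_interval_years < 1:
            raise ParameterError("intervals must be >= 1 year")

    def invites_at(self, age: int) -> bool:
        return (
            self.enabled
            and self.start_age <= age <= self.stop_age
            and (age - self.start_age) % self.interval_years == 0
        )


@dataclass
class ScreeningEventCounts:
    """Expected event counts from one screening or surveillance round."""

    gfobt_normal: float = 0.0
    gfobt_positive: float = 0.0
    colonoscopies: float = 0.0
    polypectomies: float = 0.0
    screen_detected: dict[str, float] = field(
        default_factory=lambda: {s: 0.0 for s in STAGES}
    )

    def total_screen_detected(self) -> float:
        return sum(self.screen_detected.values())


def apply_screening_round(
    occupancy: np.ndarray,
    tests: TestCharacteristics,
    behaviour: ScreeningBehaviour,
    age: float,
    uptake: float | None = None,
) -> tuple[np.ndarray, float, ScreeningEventCounts]:
    """One gFOBT screening round on an occupancy vector over the 14 states.

    With ``uptake=None`` the round handles behaviour heterogeneity internally:
    a share 1 - ever_participation never participates and the rest complete
    the test with the conditional per-round uptake (net completion equals the
    unconditional per-round uptake). Pass an explicit ``uptake`` when the
    caller already tracks behaviour groups.

    Returns ``(updated occupancy, mass entering surveillance, events)``. The
    surveillance inflow (detected high-risk-adenoma carriers, now back at
    clear epithelium) is left inside the returned occupancy; the caller moves
    it to its surveillance compartment if it tracks one.
    """
    from .natural_history import CLINICAL, PRECLINICAL, HealthState as S

    occupancy = np.asarray(occupancy, dtype=float)
    if np.any(occupancy < 0):
        raise ParameterError("occupancy has negative mass")
    if uptake is None:
        uptake = behaviour.ever_participation * behaviour.conditional_uptake
    out = occupancy.copy()
    ev = ScreeningEventCounts()

    spec = interpolate_age_curve(tests.gfobt_spec, age)
    fp_rate = 1.0 - spec
    comply = behaviour.col_followup_compliance

    # gFOBT positivity per undiagnosed state
    positivity = {
        S.CLEAR: fp_rate,
        S.LR_ADENOMA: tests.gfobt_sens["LR"],
        S.HR_ADENOMA: tests.gfobt_sens["HR"],
        S.PRE_A: tests.gfobt_sens["CRC"],
        S.PRE_B: tests.gfobt_sens["CRC"],
        S.PRE_C: tests.gfobt_sens["CRC"],
        S.PRE_D: tests.gfobt_sens["CRC"],
    }
    col_sens_by_state = {
        S.LR_ADENOMA: tests.col_sens["LR"],
        S.HR_ADENOMA: tests.col_sens["HR"],
        S.PRE_A: tests.col_sens["CRC"],
        S.PRE_B: tests.col_sens["CRC"],
        S.PRE_C: tests.col_sens["CRC"],
        S.PRE_D: tests.col_sens["CRC"],
    }

    to_surveillance = 0.0
    for state, pos_rate in positivity.items():
        screened = occupancy[state] * uptake
        positives = screened * pos_rate
        ev.gfobt_positive += positives
        ev.gfobt_normal += screened - positives
        at_col = positives * comply
        ev.colonoscopies += at_col
        if state == S.CLEAR:
            continue  # false positives: colonoscopy finds nothing (spec 1.0)
        detected = at_col * col_sens_by_state[state]
        if state == S.LR_ADENOMA:
            out[state] -= detected
            out[S.CLEAR] += detected
            ev.polypectomies += detected
        elif state == S.HR_ADENOMA:
            out[state] -= detected
            out[S.CLEAR] += detected
            ev.polypectomies += detected
            to_surveillance += detected
        else:
            stage = next(s for s in STAGES if PRECLINICAL[s] == state)
            out[state] -= detected
            out[CLINICAL[stage]] += detected
            ev.screen_detected[stage] += detected
    return out, to_surveillance, ev


def surveillance_round(
    occupancy: np.ndarray,
    tests: TestCharacteristics,
    behaviour: ScreeningBehaviour,
    programme: ScreeningProgramme,
) -> tuple[np.ndarray, ScreeningEventCounts]:
    """Annual surveillance step for the in-surveillance compartment.

    Each person receives a colonoscopy with probability
    compliance / interval_years this cycle; findings are handled as at
    follow-up colonoscopy (adenomas removed, cancer diagnosed).
    """
    from .natural_history import CLINICAL, PRECLINICAL, HealthState as S

    occupancy = np.asarray(occupancy, dtype=float)
    p_col = behaviour.col_surveillance_compliance / programme.surveillance_interval_years
    out = occupancy.copy()
    ev = ScreeningEventCounts()
    undiagnosed = [
        S.CLEAR, S.LR_ADENOMA, S.HR_ADENOMA, S.PRE_A, S.PRE_B, S.PRE_C, S.PRE_D,
    ]
    col_sens_by_state = {
        S.LR_ADENOMA: tests.col_sens["LR"],
        S.HR_ADENOMA: tests.col_sens["HR"],
        S.PRE_A: tests.col_sens["CRC"],
        S.PRE_B: tests.col_sens["CRC"],
        S.PRE_C: tests.col_sens["CRC"],
        S.PRE_D: tests.col_sens["CRC"],
    }
    for state in undiagnosed:
        at_col = occupancy[state] * p_col
        ev.colonoscopies += at_col
        if state == S.CLEAR:
            continue
        detected = at_col * col_sens_by_state[state]
        if state in (S.LR_ADENOMA, S.HR_ADENOMA):
            out[state] -= detected
            out[S.CLEAR] += detected
            ev.polypectomies += detected
        else:
            stage = next(s for s in STAGES if PRECLINICAL[s] == state)
            out[state] -= detected
            out[CLINICAL[stage]] += detected
            ev.screen_detected[stage] += detected
    return out, ev


class AdverseEventResult(NamedTuple):
    perforations: float
    perforation_deaths: float
    bleeds: float
    total_cost: float


def colonoscopy_adverse_events(
    n_colonoscopies: float,
    n_polypectomies: float,
    ae: AdverseEventParams,
) -> AdverseEventResult:
    """Expected colonoscopy harms and their cost.

    Perforation risk applies per procedure, at the with-polypectomy rate for
    polypectomy procedures and the (zero) without-polypectomy rate otherwise;
    bleeding admissions apply to every colonoscopy.
    """
    if n_colonoscopies < 0 or n_polypectomies < 0:
        raise ParameterError("procedure counts must be >= 0")
    if n_polypectomies > n_colonoscopies:
        raise ParameterError("polypectomies cannot exceed colonoscopies")
    perforations = (
        n_polypectomies * ae.perforation_prob_polypectomy
        + (n_colonoscopies - n_polypectomies) * ae.perforation_prob_no_polypectomy
    )
    perforation_deaths = perforations * ae.death_given_perforation
    bleeds = n_colonoscopies * ae.bleed_hospitalisation_prob
    cost = perforations * ae.perforation_cost + bleeds * ae.bleed_cost
    return AdverseEventResult(perforations, perforation_deaths, bleeds, cost)
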