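"""Health-economic evaluation: discounted costs, QALYs, and incremental measures.

Costs and QALYs are discounted at an annual rate (default 3.5%) with the
campaign year taking discount factor 1. Screening-related costs combine test
kits by result (with the mean-kits-completed multiplier), non-complier
handling, colonoscopies (inflated by the repeat-test rate), pathology for each
lesion or cancer found, and expected adverse-event costs. Cancer-management
costs are charged once at diagnosis and vary linearly with age at diagnosis
within the per-stage printed range. Quality of life is 0.80 cancer-free (all
alive non-diagnosed states) and 0.70 after a cancer diagnosis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .campaign import CampaignCosts
from .parameters import (
    STAGES,
    AdverseEventParams,
    EconomicParams,
    ParameterError,
    ScreeningBehaviour,
)
from .screening import colonoscopy_adverse_events

__all__ = [
    "CostBreakdown",
    "CEResult",
    "discount_factor",
    "accumulate_costs",
    "accumulate_qalys",
    "incremental_ce",
]


def discount_factor(t: float, rate: float) -> float:
    """(1 + rate)^-t; the campaign year (cycle 0) takes t = 0."""
    if t < 0:
        raise ParameterError("time must be >= 0")
    if rate < 0:
        raise ParameterError("rate must be >= 0")
    return (1.0 + rate) ** (-t)


@dataclass(frozen=True)
class CostBreakdown:
    """Discounted cost components (undiscounted twins retained)."""

    screening_related: float
    cancer_management: float
    gp_consultations_referrals: float
    campaign_delivery: float
    screening_related_undiscounted: float = 0.0
    cancer_management_undiscounted: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.screening_related
            + self.cancer_management
            + self.gp_consultations_referrals
            + self.campaign_delivery
        )

    @property
    def total_undiscounted(self) -> float:
        return (
            self.screening_related_undiscounted
            + self.cancer_management_undiscounted
            + self.gp_consultations_referrals
            + self.campaign_delivery
        )


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of a campaign against no campaign.

    ``icer`` is delta cost / delta QALY when the QALY gain is positive; a
    non-positive gain leaves it undefined (NaN) with ``dominance`` set.
    ``nmb`` is WTP x delta QALY - delta cost.
    """

    delta_cost: float
    delta_qaly: float
    delta_ly_undiscounted: float
    delta_ly_discounted: float
    deaths_prevented: float
    deaths_with_undiagnosed_crc_change: float
    wtp: float
    dominance: str = ""

    @property
    def icer(self) -> float:
        if self.delta_qaly > 0:
            return self.delta_cost / self.delta_qaly
        return float("nan")

    @property
    def nmb(self) -> float:
        return self.wtp * self.delta_qaly - self.delta_cost

    def as_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "delta_ly_undiscounted": self.delta_ly_undiscounted,
            "delta_ly_discounted": self.delta_ly_discounted,
            "deaths_prevented": self.deaths_prevented,
            "deaths_with_undiagnosed_crc_change": self.deaths_with_undiagnosed_crc_change,
            "icer": self.icer,
            "nmb": self.nmb,
            "wtp": self.wtp,
            "dominance": self.dominance,
        }


def accumulate_costs(
    trace,
    econ: EconomicParams,
    behaviour: ScreeningBehaviour | None = None,
    ae: AdverseEventParams | None = None,
    campaign_costs: CampaignCosts | None = None,
    rate: float | None = None,
) -> CostBreakdown:
    """Discounted cost breakdown for a simulated trace.

    Screening costs need ``behaviour`` (kit multipliers) and ``ae`` (harm
    costs); with no screening in the trace they are zero. Campaign delivery
    and attendance costs, if supplied, are year-0 outlays taken as given.
    """
    rate = econ.discount_rate if rate is None else rate
    T = trace.n_cycles
    disc = np.array([discount_factor(t, rate) for t in range(T)])

    counts = trace.screening_counts
    screen_per_cycle = np.zeros(T)
    if counts["invitations"].any() or counts["surveillance_colonoscopies"].any():
        if behaviour is None or ae is None:
            raise ParameterError(
                "screening activity present: behaviour and adverse-event "
                "parameters required to cost it"
            )
        n_col = counts["colonoscopies"] + counts["surveillance_colonoscopies"]
        # a fraction of colonoscopies must be repeated; detection is unaffected
        n_col_billed = n_col * (1.0 + behaviour.repeat_test_rate)
        n_found = counts["polypectomies"] + sum(
            trace.screen_diag[:, :, k].sum(axis=1) for k in range(len(STAGES))
        )
        ae_cost = np.array([
            colonoscopy_adverse_events(
                float(n_col[t]), float(counts["polypectomies"][t]), ae
            ).total_cost
            for t in range(T)
        ])
        screen_per_cycle = (
            counts["gfobt_normal"] * econ.cost_gfobt_normal
            + counts["gfobt_positive"] * econ.cost_gfobt_positive
            + counts["gfobt_noncompliers"] * econ.cost_gfobt_noncomplier
            + n_col_billed * econ.cost_colonoscopy
            + n_found * econ.cost_pathology
            + ae_cost
        )

    # cancer management: stage- and age-at-diagnosis-dependent, charged once
    ages_at_diag = trace.start_ages[None, :] + np.arange(T)[:, None]  # (T, C)
    mgmt_per_cycle = np.zeros(T)
    for k, stage in enumerate(STAGES):
        diag = trace.sympt_diag[:, :, k] + trace.screen_diag[:, :, k]
        if not diag.any():
            continue
        cost_matrix = np.vectorize(
            lambda a, s=stage: econ.treatment_cost(s, a)
        )(ages_at_diag)
        mgmt_per_cycle += (diag * cost_matrix).sum(axis=1)

    return CostBreakdown(
        screening_related=float((screen_per_cycle * disc).sum()),
        cancer_management=float((mgmt_per_cycle * disc).sum()),
        gp_consultations_referrals=(
            campaign_costs.gp_and_secondary_attendance if campaign_costs else 0.0
        ),
        campaign_delivery=(
            campaign_costs.campaign_delivery if campaign_costs else 0.0
        ),
        screening_related_undiscounted=float(screen_per_cycle.sum()),
        cancer_management_undiscounted=float(mgmt_per_cycle.sum()),
    )


def accumulate_qalys(trace, econ: EconomicParams,
                     rate: float | None = None) -> tuple[float, float, float]:
    """(undiscounted life-years, discounted life-years, discounted QALYs).

    Each cycle an alive person contributes one life-year, weighted by the
    state utility for QALYs and by the discount factor for discounted totals.
    Only cycles in which a cohort is still followed (below the age cap)
    accrue.
    """
    from .natural_history import CLINICAL, HealthState

    rate = econ.discount_rate if rate is None else rate
    T = trace.n_cycles
    disc = np.array([discount_factor(t, rate) for t in range(T)])
    clin = [int(CLINICAL[s]) for s in STAGES]
    other_alive = [
        int(s) for s in (
            HealthState.CLEAR, HealthState.LR_ADENOMA, HealthState.HR_ADENOMA,
            HealthState.PRE_A, HealthState.PRE_B, HealthState.PRE_C,
            HealthState.PRE_D,
        )
    ]
    occ = trace.occupancy[:T] * trace.active[:, :, None]  # alive accrual mask
    ly_per_cycle = occ[:, :, other_alive + clin].sum(axis=(1, 2))
    qaly_per_cycle = (
        occ[:, :, other_alive].sum(axis=(1, 2)) * econ.utility_cancer_free
        + occ[:, :, clin].sum(axis=(1, 2)) * econ.utility_crc
    )
    return (
        float(ly_per_cycle.sum()),
        float((ly_per_cycle * disc).sum()),
        float((qaly_per_cycle * disc).sum()),
    )


def incremental_ce(
    base: tuple[CostBreakdown, tuple[float, float, float], float, float],
    campaign: tuple[CostBreakdown, tuple[float, float, float], float, float],
    wtp: float,
) -> CEResult:
    """Incremental comparison: campaign minus no-campaign.

    Each argument is ``(costs, (ly_undisc, ly_disc, qaly_disc), crc_deaths,
    deaths_with_undiagnosed_crc)`` from runs on identical inputs.
    """
    costs0, (ly0u, ly0d, q0), deaths0, undiag0 = base
    costs1, (ly1u, ly1d, q1), deaths1, undiag1 = campaign
    dq = q1 - q0
    dc = costs1.total - costs0.total
    dominance = ""
    if dq <= 0:
        dominance = "dominated" if dc >= 0 else "dominating"
    return CEResult(
        delta_cost=dc,
        delta_qaly=dq,
        delta_ly_undiscounted=ly1u - ly0u,
        delta_ly_discounted=ly1d - ly0d,
        deaths_prevented=deaths0 - deaths1,
        deaths_with_undiagnosed_crc_change=undiag1 - undiag0,
        wtp=wtp,
        dominance=dominance,
    )
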