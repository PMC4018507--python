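"""Direct costs of the awareness campaign and national scaling of pilot counts."""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import CampaignScenario, ParameterError, campaign_unit_cost_per_person

__all__ = ["CampaignCosts", "campaign_direct_costs", "national_scaling",
           "DEFAULT_NATIONAL_SCALE_FACTOR"]

#: Maps the pilot's ~700 extra GP attendances to the assumed 70,000 national.
DEFAULT_NATIONAL_SCALE_FACTOR = 100.0


@dataclass(frozen=True)
class CampaignCosts:
    """Direct (non-treatment) campaign costs, incurred in the campaign year."""

    campaign_delivery: float
    gp_and_secondary_attendance: float

    def __post_init__(self) -> None:
        if self.campaign_delivery < 0 or self.gp_and_secondary_attendance < 0:
            raise ParameterError("campaign costs must be >= 0")

    @property
    def total_direct(self) -> float:
        return self.campaign_delivery + self.gp_and_secondary_attendance


def campaign_direct_costs(
    scenario: CampaignScenario, population: float
) -> CampaignCosts:
    """Delivery plus incremental attendance cost for a population.

    Both components fall in cycle 0 (discount factor 1). The attendance
    component counts only the ``proportion_additional`` share of
    campaign-induced GP and secondary-care visits.
    """
    if population <= 0:
        raise ParameterError("population must be > 0")
    delivery = scenario.campaign_cost_per_person * population
    attendance = campaign_unit_cost_per_person(scenario) * population
    return CampaignCosts(
        campaign_delivery=delivery, gp_and_secondary_attendance=attendance
    )


def national_scaling(pilot_count: float, scale_factor: float) -> float:
    """Scale a two-region pilot count to a national figure."""
    if scale_factor <= 0:
        raise ParameterError("scale_factor must be > 0")
    return pilot_count * scale_factor
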