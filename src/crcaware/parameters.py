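"""Model parameters: natural history, screening behaviour, test characteristics,
economics, and campaign scenario definitions.

All defaults transcribe the published parameter tables of the awareness-campaign
cost-effectiveness model at full printed precision. Age-dependent natural-history
probabilities are given as anchor points at ages 30/50/70/100 and interpolated
piecewise-linearly between them (the simplest scheme exact at every printed
value). gFOBT specificity has anchors at 50 and 70 only and is held flat outside
that range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "STAGES",
    "AgeCurve",
    "NaturalHistoryParams",
    "TestCharacteristics",
    "ScreeningBehaviour",
    "AdverseEventParams",
    "EconomicParams",
    "CampaignScenario",
    "ModelParameters",
    "interpolate_age_curve",
    "derive_conditional_participation",
    "equivalent_stage_restricted_multiplier",
    "campaign_unit_cost_per_person",
    "load_parameters",
    "dump_parameters",
]

#: Dukes' stages, least to most advanced.
STAGES: tuple[str, ...] = ("A", "B", "C", "D")


class ParameterError(ValueError):
    """Raised when a parameter bundle violates its invariants."""


@dataclass(frozen=True)
class AgeCurve:
    """A probability (or rate) defined by anchor points over age.

    Parameters
    ----------
    anchors
        Sequence of ``(age, value)`` pairs with strictly increasing ages.
    extrapolation
        ``"error"`` (default) raises outside the anchor range; ``"clamp"``
        holds the nearest anchor value flat.
    """

    anchors: tuple[tuple[float, float], ...]
    extrapolation: str = "error"

    def __post_init__(self) -> None:
        anchors = tuple((float(a), float(v)) for a, v in self.anchors)
        object.__setattr__(self, "anchors", anchors)
        ages = [a for a, _ in anchors]
        if len(ages) < 1:
            raise ParameterError("AgeCurve needs at least one anchor")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ParameterError("AgeCurve anchor ages must be strictly increasing")
        for _, v in anchors:
            if not math.isfinite(v):
                raise ParameterError("AgeCurve values must be finite")
        if self.extrapolation not in ("error", "clamp"):
            raise ParameterError(f"unknown extrapolation mode {self.extrapolation!r}")

    @property
    def ages(self) -> np.ndarray:
        return np.array([a for a, _ in self.anchors])

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.anchors])

    def __call__(self, age: float) -> float:
        return interpolate_age_curve(self, age)


def interpolate_age_curve(curve: AgeCurve, age: float) -> float:
    """Piecewise-linear interpolation of an :class:`AgeCurve` at ``age``.

    Exact at anchors. Outside the anchor range the behaviour follows the
    curve's ``extrapolation`` mode.
    """
    ages, values = curve.ages, curve.values
    if age < ages[0] or age > ages[-1]:
        if curve.extrapolation == "clamp":
            return float(values[0] if age < ages[0] else values[-1])
        raise ParameterError(
            f"age {age} outside anchor range [{ages[0]}, {ages[-1]}]"
        )
    return float(np.interp(age, ages, values))


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ParameterError(f"{name} = {p} is not a probability in [0, 1]")


@dataclass(frozen=True)
class NaturalHistoryParams:
    """Annual natural-history transition probabilities (adenoma-carcinoma sequence).

    ``adenoma_onset``: clear epithelium -> low-risk adenoma; ``lr_to_hr``:
    low- to high-risk adenoma; ``hr_to_crcA``: high-risk adenoma -> preclinical
    Dukes' A. ``stage_progression`` holds preclinical A->B, B->C, C->D annual
    probabilities; ``presentation`` the per-stage annual probability of
    symptomatic (or chance) presentation leading to diagnosis.
    """

    adenoma_onset: AgeCurve = AgeCurve(((30, 0.021), (50, 0.020), (70, 0.045), (100, 0.011)))
    lr_to_hr: AgeCurve = AgeCurve(((30, 0.009), (50, 0.008), (70, 0.008), (100, 0.004)))
    hr_to_crcA: AgeCurve = AgeCurve(((30, 0.029), (50, 0.025), (70, 0.054), (100, 0.115)))
    normal_to_crcA: float = 0.00004
    stage_progression: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.51, "B": 0.69, "C": 0.71}
    )
    presentation: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.04, "B": 0.18, "C": 0.37, "D": 0.74}
    )
    proximal_fraction: float = 0.38
    adenomas_per_carrier: float = 1.90
    advanced_hr_fraction: float = 0.75

    def __post_init__(self) -> None:
        for curve in (self.adenoma_onset, self.lr_to_hr, self.hr_to_crcA):
            for _, v in curve.anchors:
                _check_prob("age-curve anchor", v)
        _check_prob("normal_to_crcA", self.normal_to_crcA)
        for s, p in self.stage_progression.items():
            _check_prob(f"stage_progression[{s}]", p)
        pres = [self.presentation[s] for s in STAGES]
        for s, p in zip(STAGES, pres):
            _check_prob(f"presentation[{s}]", p)
        if not all(a < b for a, b in zip(pres, pres[1:])):
            raise ParameterError(
                "symptomatic presentation probabilities must strictly increase with stage"
            )
        _check_prob("proximal_fraction", self.proximal_fraction)
        _check_prob("advanced_hr_fraction", self.advanced_hr_fraction)


@dataclass(frozen=True)
class TestCharacteristics:
    """gFOBT and colonoscopy sensitivity/specificity.

    Sensitivities are per lesion class (low-risk adenoma, high-risk adenoma,
    CRC); gFOBT specificity is age-dependent (anchors at 50 and 70, clamped
    outside).
    """

    __test__ = False  # keep pytest from collecting this domain class

    gfobt_sens: Mapping[str, float] = field(
        default_factory=lambda: {"LR": 0.01, "HR": 0.12, "CRC": 0.24}
    )
    gfobt_spec: AgeCurve = AgeCurve(((50, 0.99), (70, 0.97)), extrapolation="clamp")
    col_sens: Mapping[str, float] = field(
        default_factory=lambda: {"LR": 0.77, "HR": 0.98, "CRC": 0.98}
    )
    col_spec: float = 1.00

    def __post_init__(self) -> None:
        for k, v in {**self.gfobt_sens, **self.col_sens}.items():
            _check_prob(f"sensitivity[{k}]", v)
        for _, v in self.gfobt_spec.anchors:
            _check_prob("gfobt_spec anchor", v)
        _check_prob("col_spec", self.col_spec)


def derive_conditional_participation(per_round: float, ever: float) -> float:
    """Per-round gFOBT uptake among people who ever participate.

    ``per_round`` is the unconditional per-round participation; ``ever`` the
    proportion completing at least one screening round. The ratio is the
    per-round uptake conditional on being an ever-participant.
    """
    if ever <= 0:
        raise ParameterError("ever-participation must be > 0")
    _check_prob("per_round", per_round)
    _check_prob("ever", ever)
    out = per_round / ever
    if out > 1.0 + 1e-12:
        raise ParameterError(
            f"per-round uptake {per_round} exceeds ever-participation {ever}"
        )
    return min(out, 1.0)


@dataclass(frozen=True)
class ScreeningBehaviour:
    per_round_uptake: float = 0.54
    ever_participation: float = 0.63
    col_followup_compliance: float = 0.79
    col_surveillance_compliance: float = 0.83
    repeat_test_rate: float = 0.07
    mean_tests_completed: float = 1.08

    def __post_init__(self) -> None:
        for name in (
            "per_round_uptake",
            "ever_participation",
            "col_followup_compliance",
            "col_surveillance_compliance",
            "repeat_test_rate",
        ):
            _check_prob(name, getattr(self, name))
        # validates per_round <= ever as a side effect
        derive_conditional_participation(self.per_round_uptake, self.ever_participation)

    @property
    def conditional_uptake(self) -> float:
        """Per-round uptake among ever-participants (printed rounded as 0.85)."""
        return derive_conditional_participation(
            self.per_round_uptake, self.ever_participation
        )


@dataclass(frozen=True)
class AdverseEventParams:
    """Colonoscopy harms: perforation (polypectomy only) and bleed admission."""

    perforation_prob_polypectomy: float = 0.003
    perforation_prob_no_polypectomy: float = 0.0
    death_given_perforation: float = 0.052
    bleed_hospitalisation_prob: float = 0.003
    perforation_cost: float = 5089.0
    bleed_cost: float = 278.0

    def __post_init__(self) -> None:
        for name in (
            "perforation_prob_polypectomy",
            "perforation_prob_no_polypectomy",
            "death_given_perforation",
            "bleed_hospitalisation_prob",
        ):
            _check_prob(name, getattr(self, name))
        if self.perforation_cost < 0 or self.bleed_cost < 0:
            raise ParameterError("adverse-event costs must be >= 0")


@dataclass(frozen=True)
class EconomicParams:
    """Utilities, discounting, willingness-to-pay, and unit costs (GBP).

    ``treatment_cost_ranges`` give per-stage (min, max) treatment costs; the
    range reflects variation with age at diagnosis. ``treatment_age_mapping``
    selects which end of the range applies at the youngest modelled age
    (default: the maximum, i.e. more aggressive treatment when young).
    """

    utility_cancer_free: float = 0.80
    utility_crc: float = 0.70
    discount_rate: float = 0.035
    wtp_threshold: float = 20_000.0
    treatment_cost_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "A": (1320.0, 8375.0),
            "B": (1479.0, 8362.0),
            "C": (1493.0, 13862.0),
            "D": (772.0, 11198.0),
        }
    )
    cost_gfobt_noncomplier: float = 2.03
    cost_gfobt_normal: float = 3.36
    cost_gfobt_positive: float = 11.94
    cost_colonoscopy: float = 563.0
    cost_pathology: float = 26.0
    treatment_age_mapping: str = "max_at_youngest"

    def __post_init__(self) -> None:
        _check_prob("utility_cancer_free", self.utility_cancer_free)
        _check_prob("utility_crc", self.utility_crc)
        if self.utility_crc >= self.utility_cancer_free:
            raise ParameterError("CRC utility must be below cancer-free utility")
        if self.discount_rate < 0:
            raise ParameterError("discount rate must be >= 0")
        for s, (lo, hi) in self.treatment_cost_ranges.items():
            if lo > hi:
                raise ParameterError(f"treatment cost range for stage {s}: min > max")
        if self.treatment_age_mapping not in ("max_at_youngest", "min_at_youngest"):
            raise ParameterError(
                f"unknown treatment_age_mapping {self.treatment_age_mapping!r}"
            )

    def treatment_cost(self, stage: str, age: float,
                       age_min: float = 30.0, age_max: float = 100.0) -> float:
        """Stage- and age-at-diagnosis-dependent treatment cost, linear in age."""
        lo, hi = self.treatment_cost_ranges[stage]
        frac = (min(max(age, age_min), age_max) - age_min) / (age_max - age_min)
        if self.treatment_age_mapping == "max_at_youngest":
            return hi + frac * (lo - hi)
        return lo + frac * (hi - lo)


@dataclass(frozen=True)
class CampaignScenario:
    """An awareness-campaign intervention.

    ``stage_multipliers`` are fractional increases in the symptomatic/chance
    presentation rate per Dukes' stage (base case 0.10 for all four), applied
    for ``duration_months`` of the first model year. Direct costs cover
    campaign delivery plus the extra GP and secondary-care attendances it
    generates; ``proportion_additional`` is the share of those visits that are
    genuinely extra rather than merely earlier.
    """

    stage_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.10, "B": 0.10, "C": 0.10, "D": 0.10}
    )
    duration_months: int = 1
    campaign_cost_per_person: float = 0.14
    gp_attendances_per_person: float = 0.0014
    secondary_appointments_per_person: float = 1.52606e-5
    gp_visit_cost: float = 36.0
    secondary_visit_cost: float = 200.0
    proportion_additional: float = 0.5

    def __post_init__(self) -> None:
        for s, m in self.stage_multipliers.items():
            if m < 0:
                raise ParameterError(f"stage multiplier for {s} must be >= 0")
        if not (self.duration_months == 0 or 1 <= self.duration_months <= 12):
            raise ParameterError(
                f"duration_months = {self.duration_months} outside [1, 12] (0 = null scenario)"
            )
        _check_prob("proportion_additional", self.proportion_additional)

    @property
    def is_null(self) -> bool:
        return self.duration_months == 0 or all(
            m == 0 for m in self.stage_multipliers.values()
        )

    def restricted_to(self, stages: Iterable[str],
                      multiplier: float | None = None) -> "CampaignScenario":
        """Scenario with the presentation increase confined to ``stages``."""
        stages = set(stages)
        mult = {
            s: (multiplier if multiplier is not None else self.stage_multipliers[s])
            if s in stages else 0.0
            for s in STAGES
        }
        return replace(self, stage_multipliers=mult)


def equivalent_stage_restricted_multiplier(
    all_stage_increase: float,
    stage_distribution: Mapping[str, float],
    restricted_stages: Iterable[str],
) -> float:
    """Uniform increase on a stage subset matching a given all-stage incidence rise.

    If symptomatic incidence splits across stages as ``stage_distribution``,
    raising presentation on only ``restricted_stages`` by the returned fraction
    produces the same total incidence increase as raising all stages by
    ``all_stage_increase`` (e.g. 10% all-stage with C+D carrying 65% of
    incidence requires ~15.4% on C and D).
    """
    restricted = set(restricted_stages)
    if not restricted:
        raise ParameterError("restricted stage set must be non-empty")
    total = sum(stage_distribution.values())
    # printed stage shares may carry rounding (e.g. 11+25+36+29 = 101%)
    if abs(total - 1.0) > 0.02:
        raise ParameterError(f"stage distribution sums to {total}, not 1")
    share = sum(v for s, v in stage_distribution.items() if s in restricted)
    if share == 0:
        raise ParameterError("restricted stages carry zero incidence share")
    return all_stage_increase / share


def campaign_unit_cost_per_person(scenario: CampaignScenario) -> float:
    """Expected incremental GP + secondary-care attendance cost per person.

    Only the ``proportion_additional`` share of campaign-induced visits is
    costed; the remainder are visits that would have happened anyway, earlier.
    """
    return scenario.proportion_additional * (
        scenario.gp_attendances_per_person * scenario.gp_visit_cost
        + scenario.secondary_appointments_per_person * scenario.secondary_visit_cost
    )


@dataclass(frozen=True)
class ModelParameters:
    """The full parameter bundle used by the simulation pipeline."""

    natural_history: NaturalHistoryParams = NaturalHistoryParams()
    tests: TestCharacteristics = TestCharacteristics()
    behaviour: ScreeningBehaviour = ScreeningBehaviour()
    adverse_events: AdverseEventParams = AdverseEventParams()
    economics: EconomicParams = EconomicParams()
    campaign: CampaignScenario = CampaignScenario()


# ---------------------------------------------------------------------------
# Flat-file (YAML) serialization. One canonical file ships with the package
# transcribing the published tables; unknown keys are rejected.
# ---------------------------------------------------------------------------

_SECTIONS = {
    "natural_history": NaturalHistoryParams,
    "tests": TestCharacteristics,
    "behaviour": ScreeningBehaviour,
    "adverse_events": AdverseEventParams,
    "economics": EconomicParams,
    "campaign": CampaignScenario,
}

_CURVE_FIELDS = {
    ("natural_history", "adenoma_onset"): "error",
    ("natural_history", "lr_to_hr"): "error",
    ("natural_history", "hr_to_crcA"): "error",
    ("tests", "gfobt_spec"): "clamp",
}


def _params_to_dict(params: ModelParameters) -> dict:
    out: dict = {}
    for section, cls in _SECTIONS.items():
        raw = asdict(getattr(params, section))
        for key, val in list(raw.items()):
            if (section, key) in _CURVE_FIELDS:
                raw[key] = {"anchors": [list(a) for a in val["anchors"]]}
            elif isinstance(val, tuple):
                raw[key] = list(val)
            elif isinstance(val, dict):
                raw[key] = {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in val.items()}
        out[section] = raw
    return out


def _dict_to_params(data: Mapping) -> ModelParameters:
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ParameterError(f"unknown configuration section(s): {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        raw = dict(data.get(section, {}))
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(
                f"unknown key(s) in section {section!r}: {sorted(unknown)}"
            )
        for key in list(raw):
            if (section, key) in _CURVE_FIELDS:
                raw[key] = AgeCurve(
                    tuple(tuple(a) for a in raw[key]["anchors"]),
                    extrapolation=_CURVE_FIELDS[(section, key)],
                )
            elif key == "treatment_cost_ranges":
                raw[key] = {s: tuple(v) for s, v in raw[key].items()}
        kwargs[section] = cls(**raw)
    return ModelParameters(**kwargs)


def load_parameters(path=None) -> ModelParameters:
    """Load a parameter file; with no path, the canonical shipped file."""
    import yaml

    if path is None:
        from importlib.resources import files

        text = files("crcaware.data").joinpath("parameters.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    data = yaml.safe_load(text) or {}
    return _dict_to_params(data)


def dump_parameters(params: ModelParameters, path=None) -> str:
    """Serialize a parameter bundle to YAML; round-trips exactly."""
    import yaml

    text = yaml.safe_dump(_params_to_dict(params), sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
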