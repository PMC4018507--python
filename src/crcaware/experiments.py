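"""The experiment set: base case, sensitivity grid, PSA, uptake equivalence.

Every experiment compares an awareness-campaign scenario against "no campaign"
on identical inputs and reports the incremental health-economic result. The
probabilistic sensitivity analysis samples natural-history probabilities, test
characteristics and utilities from Beta distributions and unit costs from
Gamma distributions around their table means (default standard error 10% of
the mean), re-running the incremental comparison per draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .campaign import campaign_direct_costs
from .economics import (
    CEResult,
    CostBreakdown,
    accumulate_costs,
    accumulate_qalys,
    incremental_ce,
)
from .natural_history import run_population
from .parameters import (
    STAGES,
    AdverseEventParams,
    AgeCurve,
    CampaignScenario,
    EconomicParams,
    ModelParameters,
    NaturalHistoryParams,
    ParameterError,
    ScreeningBehaviour,
    TestCharacteristics,
    equivalent_stage_restricted_multiplier,
)
from .screening import ScreeningProgramme
from .synthetic_data import (
    Demography,
    SurvivalFixture,
    make_demography_fixture,
    make_survival_fixture,
)

__all__ = [
    "ModelInputs",
    "BaseCaseResult",
    "GridResult",
    "PSAResult",
    "SYMPTOMATIC_STAGE_SHARES",
    "run_base_case",
    "run_sensitivity_grid",
    "run_psa",
    "screening_uptake_equivalence",
]

#: Symptomatic-incidence stage shares used for the matched-incidence
#: stage-restricted scenario (Dukes' A-D).
SYMPTOMATIC_STAGE_SHARES: dict[str, float] = {"A": 0.11, "B": 0.25, "C": 0.36, "D": 0.29}


@dataclass(frozen=True)
class ModelInputs:
    """Everything a simulation run needs besides the campaign scenario."""

    params: ModelParameters = field(default_factory=ModelParameters)
    demography: Demography = field(default_factory=make_demography_fixture)
    survival: SurvivalFixture = field(default_factory=make_survival_fixture)
    programme: ScreeningProgramme = field(default_factory=ScreeningProgramme)
    #: population used as the denominator for per-person campaign costs;
    #: None uses the modelled 30+ population.
    cost_population: float | None = None

    @property
    def campaign_cost_population(self) -> float:
        if self.cost_population is not None:
            return self.cost_population
        return self.demography.total_population


@dataclass(frozen=True)
class BaseCaseResult:
    ce: CEResult
    costs_base: CostBreakdown
    costs_campaign: CostBreakdown
    sympt_diag_change_by_stage: dict[str, float]
    screen_diag_change_by_stage: dict[str, float]

    def summary_frame(self) -> pd.DataFrame:
        """Outcome table in the shape of the published prediction table."""
        rows = []
        for s in STAGES:
            rows.append((f"CRC incidence symptomatic, Dukes' {s}",
                         self.sympt_diag_change_by_stage[s]))
        rows.append(("CRC incidence symptomatic, total",
                     sum(self.sympt_diag_change_by_stage.values())))
        for s in STAGES:
            rows.append((f"CRC incidence screen/surveillance, Dukes' {s}",
                         self.screen_diag_change_by_stage[s]))
        rows.append(("CRC incidence screen/surveillance, total",
                     sum(self.screen_diag_change_by_stage.values())))
        rows.append(("CRC-specific deaths", -self.ce.deaths_prevented))
        rows.append(("Deaths with undiagnosed CRC",
                     self.ce.deaths_with_undiagnosed_crc_change))
        dc = self.costs_campaign
        db = self.costs_base
        rows.append(("Screening-related costs (discounted)",
                     dc.screening_related - db.screening_related))
        rows.append(("Cancer management costs (discounted)",
                     dc.cancer_management - db.cancer_management))
        rows.append(("GP consultations/referrals cost",
                     dc.gp_consultations_referrals - db.gp_consultations_referrals))
        rows.append(("Campaign cost", dc.campaign_delivery - db.campaign_delivery))
        rows.append(("Total cost (discounted)", self.ce.delta_cost))
        rows.append(("Life-years gained (undiscounted)", self.ce.delta_ly_undiscounted))
        rows.append(("Life-years gained (discounted)", self.ce.delta_ly_discounted))
        rows.append(("QALYs gained (discounted)", self.ce.delta_qaly))
        rows.append(("ICER", self.ce.icer))
        rows.append(("NMB", self.ce.nmb))
        return pd.DataFrame(rows, columns=["outcome", "change_vs_no_campaign"])


def _evaluate(
    inputs: ModelInputs,
    campaign: CampaignScenario | None,
    stage_restricted_to: Sequence[str] | None = None,
    behaviour: ScreeningBehaviour | None = None,
):
    """Run one scenario and return (trace, costs, qalys, deaths, undiag deaths)."""
    p = inputs.params
    behaviour = behaviour if behaviour is not None else p.behaviour
    trace = run_population(
        demography=inputs.demography,
        nh=p.natural_history,
        survival=inputs.survival,
        tests=p.tests,
        behaviour=behaviour,
        programme=inputs.programme,
        campaign=campaign,
        stage_restricted_to=stage_restricted_to,
    )
    cc = None
    if campaign is not None:
        cc = campaign_direct_costs(campaign, inputs.campaign_cost_population)
        if campaign.is_null:
            # a campaign with no presentation effect generates no extra
            # attendances, but delivery is still paid (worst case: ICER -> inf)
            cc = replace_attendance_zero(cc)
    costs = accumulate_costs(
        trace, p.economics, behaviour=behaviour, ae=p.adverse_events,
        campaign_costs=cc,
    )
    qalys = accumulate_qalys(trace, p.economics)
    return trace, costs, qalys, trace.total_crc_deaths(), trace.total_deaths_undiagnosed()


def replace_attendance_zero(cc):
    from .campaign import CampaignCosts

    return CampaignCosts(campaign_delivery=cc.campaign_delivery,
                         gp_and_secondary_attendance=0.0)


def run_base_case(
    inputs: ModelInputs,
    scenario: CampaignScenario | None = None,
    stage_restricted_to: Sequence[str] | None = None,
    _base_eval=None,
) -> BaseCaseResult:
    """No-campaign vs campaign on identical inputs; full incremental result."""
    scenario = scenario if scenario is not None else inputs.params.campaign
    base = _base_eval if _base_eval is not None else _evaluate(inputs, None)
    camp = _evaluate(inputs, scenario, stage_restricted_to=stage_restricted_to)
    ce = incremental_ce(
        (base[1], base[2], base[3], base[4]),
        (camp[1], camp[2], camp[3], camp[4]),
        wtp=inputs.params.economics.wtp_threshold,
    )
    sympt0 = base[0].cumulative_symptomatic_by_stage()
    sympt1 = camp[0].cumulative_symptomatic_by_stage()
    scr0 = base[0].cumulative_screen_detected_by_stage()
    scr1 = camp[0].cumulative_screen_detected_by_stage()
    return BaseCaseResult(
        ce=ce,
        costs_base=base[1],
        costs_campaign=camp[1],
        sympt_diag_change_by_stage={
            s: float(sympt1[k] - sympt0[k]) for k, s in enumerate(STAGES)
        },
        screen_diag_change_by_stage={
            s: float(scr1[k] - scr0[k]) for k, s in enumerate(STAGES)
        },
    )


@dataclass(frozen=True)
class GridResult:
    """Two-way sensitivity over campaign duration and magnitude."""

    table: pd.DataFrame  # duration_months, magnitude, deaths_prevented, qaly_gain, icer

    def cell(self, duration: int, magnitude: float) -> pd.Series:
        m = self.table
        row = m[(m.duration_months == duration) & (np.isclose(m.magnitude, magnitude))]
        if row.empty:
            raise KeyError((duration, magnitude))
        return row.iloc[0]


def run_sensitivity_grid(
    inputs: ModelInputs,
    durations: Sequence[int] = (1, 3, 6),
    magnitudes: Sequence[float] = (0.05, 0.10, 0.20),
    stage_restricted: bool = False,
) -> GridResult:
    """One incremental comparison per (duration, magnitude) cell.

    With ``stage_restricted`` the magnitude applies to Dukes' C and D only,
    mirroring the scenario in which only late-stage presentation responds.
    """
    if not durations or not magnitudes:
        raise ParameterError("grid axes must be non-empty")
    base_eval = _evaluate(inputs, None)
    rows = []
    for d in durations:
        for m in magnitudes:
            scenario = replace_scenario(inputs.params.campaign, d, m)
            res = run_base_case(
                inputs,
                scenario,
                stage_restricted_to=("C", "D") if stage_restricted else None,
                _base_eval=base_eval,
            )
            rows.append(
                {
                    "duration_months": d,
                    "magnitude": m,
                    "deaths_prevented": res.ce.deaths_prevented,
                    "qaly_gain": res.ce.delta_qaly,
                    "icer": res.ce.icer,
                }
            )
    return GridResult(table=pd.DataFrame(rows))


def replace_scenario(base: CampaignScenario, duration: int, magnitude: float):
    return replace(
        base,
        duration_months=duration,
        stage_multipliers={s: magnitude for s in STAGES},
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


def _beta_draw(rng, mean: float, rel_se: float) -> float:
    """Beta sample with the given mean and sd = rel_se * mean (capped valid)."""
    if rel_se == 0 or mean in (0.0, 1.0):
        return mean
    sd = rel_se * mean
    cap = 0.5 * np.sqrt(mean * (1.0 - mean))
    sd = min(sd, cap)
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def _gamma_draw(rng, mean: float, rel_se: float) -> float:
    """Gamma sample with the given mean and sd = rel_se * mean."""
    if rel_se == 0 or mean == 0:
        return mean
    shape = 1.0 / rel_se**2
    return float(rng.gamma(shape, mean / shape))


def _sample_curve(rng, curve: AgeCurve, rel_se: float) -> AgeCurve:
    return AgeCurve(
        tuple((a, _beta_draw(rng, v, rel_se)) for a, v in curve.anchors),
        extrapolation=curve.extrapolation,
    )


def sample_model_parameters(
    params: ModelParameters, rng: np.random.Generator, rel_se: float = 0.10
) -> ModelParameters:
    """One PSA draw of the uncertain parameters.

    Probabilities and utilities are Beta, costs Gamma, all with standard error
    ``rel_se`` x mean. Stage-ordered presentation probabilities are sorted
    after sampling to preserve their monotonicity constraint, and per-round
    screening uptake is derived as conditional uptake x ever-participation so
    the behaviour invariants hold by construction. ``rel_se = 0`` returns the
    parameters unchanged (degenerate distributions).
    """
    if rel_se == 0:
        return params
    nh = params.natural_history
    pres = sorted(_beta_draw(rng, nh.presentation[s], rel_se) for s in STAGES)
    nh_new = replace(
        nh,
        adenoma_onset=_sample_curve(rng, nh.adenoma_onset, rel_se),
        lr_to_hr=_sample_curve(rng, nh.lr_to_hr, rel_se),
        hr_to_crcA=_sample_curve(rng, nh.hr_to_crcA, rel_se),
        normal_to_crcA=_beta_draw(rng, nh.normal_to_crcA, rel_se),
        stage_progression={
            s: _beta_draw(rng, p, rel_se) for s, p in nh.stage_progression.items()
        },
        presentation=dict(zip(STAGES, pres)),
    )
    t = params.tests
    tests_new = replace(
        t,
        gfobt_sens={k: _beta_draw(rng, v, rel_se) for k, v in t.gfobt_sens.items()},
        gfobt_spec=_sample_curve(rng, t.gfobt_spec, rel_se),
        col_sens={k: _beta_draw(rng, v, rel_se) for k, v in t.col_sens.items()},
    )
    b = params.behaviour
    ever = _beta_draw(rng, b.ever_participation, rel_se)
    conditional = _beta_draw(rng, b.conditional_uptake, rel_se)
    behaviour_new = replace(
        b,
        ever_participation=ever,
        per_round_uptake=conditional * ever,
        col_followup_compliance=_beta_draw(rng, b.col_followup_compliance, rel_se),
        col_surveillance_compliance=_beta_draw(
            rng, b.col_surveillance_compliance, rel_se
        ),
    )
    e = params.economics
    u_free = _beta_draw(rng, e.utility_cancer_free, rel_se)
    u_crc = min(_beta_draw(rng, e.utility_crc, rel_se), u_free - 1e-9)
    econ_new = replace(
        e,
        utility_cancer_free=u_free,
        utility_crc=u_crc,
        treatment_cost_ranges={
            s: tuple(
                sorted(
                    (_gamma_draw(rng, lo, rel_se), _gamma_draw(rng, hi, rel_se))
                )
            )
            for s, (lo, hi) in e.treatment_cost_ranges.items()
        },
        cost_gfobt_noncomplier=_gamma_draw(rng, e.cost_gfobt_noncomplier, rel_se),
        cost_gfobt_normal=_gamma_draw(rng, e.cost_gfobt_normal, rel_se),
        cost_gfobt_positive=_gamma_draw(rng, e.cost_gfobt_positive, rel_se),
        cost_colonoscopy=_gamma_draw(rng, e.cost_colonoscopy, rel_se),
        cost_pathology=_gamma_draw(rng, e.cost_pathology, rel_se),
    )
    return replace(
        params,
        natural_history=nh_new,
        tests=tests_new,
        behaviour=behaviour_new,
        economics=econ_new,
    )


@dataclass(frozen=True)
class PSAResult:
    n_samples: int
    seed: int
    samples: pd.DataFrame
    deterministic: dict[str, float]

    def interval(self, output: str, lo: float = 2.5, hi: float = 97.5):
        vals = self.samples[output].to_numpy()
        return float(np.percentile(vals, lo)), float(np.percentile(vals, hi))

    def intervals(self) -> dict[str, tuple[float, float]]:
        return {c: self.interval(c) for c in self.samples.columns}


_PSA_OUTPUTS = ("deaths_prevented", "qaly_gain", "delta_cost", "icer", "nmb")


def run_psa(
    inputs: ModelInputs,
    scenario: CampaignScenario | None = None,
    n_samples: int = 1000,
    seed: int = 0,
    rel_se: float = 0.10,
) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty.

    Each draw samples one parameter set, runs campaign vs no campaign on it,
    and records the incremental outputs; 2.5/97.5 percentile intervals come
    from :meth:`PSAResult.intervals`. ``rel_se = 0`` makes every draw equal to
    the deterministic run.
    """
    if n_samples < 2:
        raise ParameterError("n_samples must be >= 2")
    scenario = scenario if scenario is not None else inputs.params.campaign
    det = run_base_case(inputs, scenario)
    det_out = {
        "deaths_prevented": det.ce.deaths_prevented,
        "qaly_gain": det.ce.delta_qaly,
        "delta_cost": det.ce.delta_cost,
        "icer": det.ce.icer,
        "nmb": det.ce.nmb,
    }
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_samples):
        sampled = sample_model_parameters(inputs.params, rng, rel_se)
        draw_inputs = replace(inputs, params=sampled)
        res = run_base_case(draw_inputs, scenario)
        rows.append(
            {
                "deaths_prevented": res.ce.deaths_prevented,
                "qaly_gain": res.ce.delta_qaly,
                "delta_cost": res.ce.delta_cost,
                "icer": res.ce.icer,
                "nmb": res.ce.nmb,
            }
        )
    return PSAResult(
        n_samples=n_samples,
        seed=seed,
        samples=pd.DataFrame(rows, columns=list(_PSA_OUTPUTS)),
        deterministic=det_out,
    )


def screening_uptake_equivalence(
    inputs: ModelInputs,
    target_qaly_gain: float,
    tol: float = 0.5,
    max_iter: int = 40,
) -> dict[str, float]:
    """Never-attender reduction matching a target QALY gain, by bisection.

    Moves a fraction of the never-attender group into the ever-attender group
    (no campaign) until the discounted QALY gain over the unmodified
    no-campaign run equals ``target_qaly_gain`` within ``tol`` QALYs. Returns
    the relative reduction of the never group, the percentage-point change,
    and the achieved gain.
    """
    if target_qaly_gain < 0:
        raise ParameterError("target_qaly_gain must be >= 0")
    b = inputs.params.behaviour
    never0 = 1.0 - b.ever_participation
    base = _evaluate(inputs, None)
    q0 = base[2][2]

    def gain(reduction: float) -> float:
        if reduction == 0:
            return 0.0
        ever_new = b.ever_participation + never0 * reduction
        behaviour_new = replace(
            b,
            ever_participation=ever_new,
            per_round_uptake=b.conditional_uptake * ever_new,
        )
        alt = _evaluate(inputs, None, behaviour=behaviour_new)
        return alt[2][2] - q0

    if target_qaly_gain == 0:
        return {
            "relative_reduction": 0.0,
            "percentage_point_change": 0.0,
            "achieved_qaly_gain": 0.0,
        }
    lo, hi = 0.0, 1.0
    g_hi = gain(hi)
    if g_hi < target_qaly_gain - tol:
        raise ParameterError(
            f"target QALY gain {target_qaly_gain} unattainable: eliminating "
            f"the never-attender group gains only {g_hi:.1f}"
        )
    x = 0.5
    for _ in range(max_iter):
        x = 0.5 * (lo + hi)
        g = gain(x)
        if abs(g - target_qaly_gain) <= tol:
            break
        if g < target_qaly_gain:
            lo = x
        else:
            hi = x
    return {
        "relative_reduction": x,
        "percentage_point_change": never0 * x * 100.0,
        "achieved_qaly_gain": gain(x),
    }
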