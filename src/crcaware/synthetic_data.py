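"""Synthetic fixtures for inputs the simulation needs but no table prints.

Three families of fixture:

* **Demography** — an England-like age pyramid for ages 30-100 with a
  Gompertz all-cause mortality schedule. These are deliberately simple,
  versioned stand-ins, not life-table transcriptions.
* **Stage-specific CRC survival** — annual cancer-death probabilities by
  Dukes' stage and year since diagnosis, ordered so prognosis worsens A -> D
  (5-year survival roughly 94/81/48/10 %, in line with the broad shape of
  English stage-specific survival but not fitted to any registry).
* **Pilot-style monthly incidence series** — seeded Poisson counts with an
  optional one-month multiplicative step, emulating the monthly registry
  series a campaign evaluation would analyse.

All generators are pure functions of their arguments (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .parameters import STAGES
from .pilot_analysis import PilotSeries

__all__ = [
    "AGE_MIN",
    "AGE_MAX",
    "Demography",
    "SurvivalFixture",
    "PilotSeriesSpec",
    "make_demography_fixture",
    "make_survival_fixture",
    "generate_pilot_incidence_series",
]

AGE_MIN = 30
AGE_MAX = 100


@dataclass(frozen=True)
class Demography:
    """Population and annual all-cause death probability per single year of age."""

    ages: np.ndarray
    population: np.ndarray
    all_cause_mortality: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        pop = np.asarray(self.population, dtype=float)
        mort = np.asarray(self.all_cause_mortality, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "population", pop)
        object.__setattr__(self, "all_cause_mortality", mort)
        if not (ages.shape == pop.shape == mort.shape):
            raise ValueError("ages, population and mortality must align")
        if np.any(pop < 0):
            raise ValueError("population must be non-negative")
        if np.any((mort < 0) | (mort > 1)):
            raise ValueError("mortality must be a probability")

    @property
    def total_population(self) -> float:
        return float(self.population.sum())

    def mortality_at(self, age: float) -> float:
        """Annual death probability at (integer-clamped) age."""
        idx = int(np.clip(round(age), self.ages[0], self.ages[-1])) - int(self.ages[0])
        return float(self.all_cause_mortality[idx])

    def population_at(self, age: int) -> float:
        return float(self.population[int(age) - int(self.ages[0])])


def make_demography_fixture(
    total_population: float = 33e6, shape: str = "england_like"
) -> Demography:
    """Deterministic age pyramid over ages 30-100 with Gompertz mortality.

    ``"england_like"`` uses a plateau through midlife and an accelerating
    decline at older ages so the pyramid's broad proportions resemble the
    adult population of England; ``"uniform"`` spreads people evenly. Both
    carry the same Gompertz mortality (hazard a0*exp(b*age) with a0, b chosen
    so annual death probability is ~5e-4 at 30 and ~0.32 at 100).
    """
    if total_population <= 0:
        raise ValueError("total_population must be > 0")
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    if shape == "england_like":
        weights = np.where(
            ages <= 60,
            1.0,
            np.exp(-((ages - 60) / 22.0) ** 2),
        )
    elif shape == "uniform":
        weights = np.ones_like(ages, dtype=float)
    else:
        raise ValueError(f"unknown demography preset {shape!r}")
    population = total_population * weights / weights.sum()

    b = 0.095
    a0 = 5e-4 / np.exp(b * AGE_MIN)  # hazard 5e-4 at age 30
    hazard = a0 * np.exp(b * ages)
    mortality = 1.0 - np.exp(-hazard)
    return Demography(ages=ages, population=population, all_cause_mortality=mortality)


@dataclass(frozen=True)
class SurvivalFixture:
    """Annual CRC-death probability by Dukes' stage and year since diagnosis.

    ``annual_death_prob[stage]`` covers years 1..n since diagnosis;
    ``beyond`` applies thereafter. The engine, which does not track time since
    diagnosis, uses :meth:`constant_annual_probability` — the constant annual
    probability with the same 5-year survival as the banded schedule.
    """

    annual_death_prob: Mapping[str, np.ndarray]
    beyond: Mapping[str, float]

    def __post_init__(self) -> None:
        probs = {s: np.asarray(v, dtype=float) for s, v in self.annual_death_prob.items()}
        object.__setattr__(self, "annual_death_prob", probs)
        for s in STAGES:
            if s not in probs:
                raise ValueError(f"missing stage {s}")
            if np.any((probs[s] < 0) | (probs[s] > 1)):
                raise ValueError("death probabilities must be in [0, 1]")
        lengths = {len(v) for v in probs.values()}
        if len(lengths) != 1:
            raise ValueError("all stages need the same number of year bands")

    def five_year_survival(self, stage: str) -> float:
        return float(np.prod(1.0 - self.annual_death_prob[stage][:5]))

    def constant_annual_probability(self, stage: str) -> float:
        """Constant annual CRC-death probability matching 5-year survival."""
        s5 = self.five_year_survival(stage)
        if s5 <= 0:
            return 1.0
        return 1.0 - s5 ** (1.0 / 5.0)


def _load_default_survival() -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Read the versioned synthetic survival table shipped with the package."""
    import csv
    from importlib.resources import files

    text = files("crcaware.data").joinpath("survival_default.csv").read_text()
    rows = [r for r in text.splitlines() if r and not r.startswith("#")]
    reader = csv.DictReader(rows)
    probs: dict[str, np.ndarray] = {}
    beyond: dict[str, float] = {}
    for row in reader:
        stage = row["stage"]
        probs[stage] = np.array(
            [float(row[f"year{y}"]) for y in range(1, 6)]
        )
        beyond[stage] = float(row["beyond"])
    return probs, beyond


def make_survival_fixture(preset: str = "default") -> SurvivalFixture:
    """Named stage-specific survival fixture.

    ``"default"`` loads the synthetic table shipped as
    ``data/survival_default.csv`` (prognosis strictly worsening A -> D; these
    are constructed values, not transcriptions of any registry). ``"null"``
    sets every CRC-death probability to zero (so a campaign can gain no
    life-years, a useful degenerate check).
    """
    if preset == "default":
        probs, beyond = _load_default_survival()
        return SurvivalFixture(annual_death_prob=probs, beyond=beyond)
    if preset == "null":
        zeros = {s: np.zeros(5) for s in STAGES}
        return SurvivalFixture(annual_death_prob=zeros, beyond={s: 0.0 for s in STAGES})
    raise ValueError(f"unknown survival preset {preset!r}")


@dataclass(frozen=True)
class PilotSeriesSpec:
    """Specification for a synthetic monthly incidence series.

    ``baseline_mean`` may be a scalar (one region) or one value per region.
    Counts are Poisson; the month at ``step_month_index`` has its mean
    multiplied by ``step_multiplier`` in every region.
    """

    n_months: int = 24
    baseline_mean: float | Sequence[float] = 300.0
    step_month_index: int = 14
    step_multiplier: float = 1.10
    seed: int = 0
    regions: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        means = np.atleast_1d(np.asarray(self.baseline_mean, dtype=float))
        if np.any(means <= 0):
            raise ValueError("baseline_mean must be > 0")
        if not (0 <= self.step_month_index < self.n_months):
            raise ValueError("step_month_index outside the series")
        if self.step_multiplier < 0:
            raise ValueError("step_multiplier must be >= 0")
        if self.regions is not None and len(self.regions) != means.size:
            raise ValueError("one region name per baseline mean required")

    @property
    def means(self) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.baseline_mean, dtype=float))

    @property
    def region_names(self) -> tuple[str, ...]:
        if self.regions is not None:
            return tuple(self.regions)
        n = self.means.size
        return tuple(f"region_{i + 1}" for i in range(n))


def generate_pilot_incidence_series(spec: PilotSeriesSpec) -> PilotSeries:
    """Seeded Poisson monthly counts with an optional one-month step."""
    rng = np.random.default_rng(spec.seed)
    means = spec.means
    lam = np.tile(means[:, None], (1, spec.n_months)).astype(float)
    lam[:, spec.step_month_index] *= spec.step_multiplier
    counts = rng.poisson(lam)
    return PilotSeries(
        counts=counts,
        regions=spec.region_names,
        campaign_start=spec.step_month_index,
    )
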