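"""Configuration, manifests, and the reproducible run pipeline.

One flat YAML configuration file drives a run: which experiment(s) to execute,
the campaign scenario, fixture presets, and the seed. The schema is validated
up front (unknown keys and out-of-range values are rejected with the offending
field named). Every run writes its result tables (CSV/JSON) plus a manifest
recording the config hash, seed, fixture presets and package version, so that
re-running an identical manifest reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .campaign import DEFAULT_NATIONAL_SCALE_FACTOR
from .experiments import (
    ModelInputs,
    run_base_case,
    run_psa,
    run_sensitivity_grid,
    screening_uptake_equivalence,
)
from .parameters import CampaignScenario, ModelParameters, load_parameters
from .pilot_analysis import PilotSeries, pooled_and_regional_tests
from .screening import ScreeningProgramme
from .synthetic_data import (
    PilotSeriesSpec,
    generate_pilot_incidence_series,
    make_demography_fixture,
    make_survival_fixture,
)

logger = logging.getLogger("crcaware")

__all__ = ["RunConfig", "RunManifest", "build_inputs", "run_pipeline", "load_config"]


class CampaignConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    magnitude: float = Field(0.10, ge=0)
    duration_months: int = 1
    stage_restricted: bool = False
    proportion_additional: float = Field(0.5, ge=0, le=1)

    @model_validator(mode="after")
    def _check_duration(self):
        if not (self.duration_months == 0 or 1 <= self.duration_months <= 12):
            raise ValueError(
                "duration_months must be 0 (null scenario) or between 1 and 12"
            )
        return self


class DemographyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    total_population: float = Field(33e6, gt=0)
    shape: Literal["england_like", "uniform"] = "england_like"


class ScreeningConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    enabled: bool = True
    start_age: int = Field(60, ge=30, le=100)
    stop_age: int = Field(69, ge=30, le=100)
    interval_years: int = Field(2, ge=1)
    surveillance_interval_years: int = Field(3, ge=1)


class PSAConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_samples: int = Field(1000, ge=2)
    rel_se: float = Field(0.10, ge=0)


class PilotConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_months: int = Field(24, ge=4)
    baseline_means: list[float] = Field(default_factory=lambda: [170.0, 130.0])
    step_month_index: int = 14
    step_multiplier: float = Field(1.10, ge=0)
    regions: list[str] | None = None
    national_scale_factor: float = Field(DEFAULT_NATIONAL_SCALE_FACTOR, gt=0)


class RunConfig(BaseModel):
    """Validated run configuration (flat YAML file)."""

    model_config = ConfigDict(extra="forbid")

    experiments: list[
        Literal["base-case", "grid", "psa", "uptake-equivalence", "pilot-stats"]
    ] = Field(default_factory=lambda: ["base-case"])
    seed: int = 0
    output_dir: str = "results"
    parameters_file: str | None = None
    survival_preset: Literal["default", "null"] = "default"
    campaign: CampaignConfig = Field(default_factory=CampaignConfig)
    demography: DemographyConfig = Field(default_factory=DemographyConfig)
    screening: ScreeningConfig = Field(default_factory=ScreeningConfig)
    psa: PSAConfig = Field(default_factory=PSAConfig)
    pilot: PilotConfig = Field(default_factory=PilotConfig)
    grid_durations: list[int] = Field(default_factory=lambda: [1, 3, 6])
    grid_magnitudes: list[float] = Field(default_factory=lambda: [0.05, 0.10, 0.20])
    uptake_target_qaly_gain: float | None = None


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def build_scenario(cfg: RunConfig, params: ModelParameters) -> CampaignScenario:
    base = params.campaign
    scenario = replace(
        base,
        stage_multipliers={s: cfg.campaign.magnitude for s in "ABCD"},
        duration_months=cfg.campaign.duration_months,
        proportion_additional=cfg.campaign.proportion_additional,
    )
    return scenario


def build_inputs(cfg: RunConfig) -> ModelInputs:
    """Assemble model inputs (parameters + fixtures) from a config."""
    params = load_parameters(cfg.parameters_file)
    return ModelInputs(
        params=params,
        demography=make_demography_fixture(
            cfg.demography.total_population, cfg.demography.shape
        ),
        survival=make_survival_fixture(cfg.survival_preset),
        programme=ScreeningProgramme(
            start_age=cfg.screening.start_age,
            stop_age=cfg.screening.stop_age,
            interval_years=cfg.screening.interval_years,
            surveillance_interval_years=cfg.screening.surveillance_interval_years,
            enabled=cfg.screening.enabled,
        ),
    )


@dataclass(frozen=True)
class RunManifest:
    config_hash: str
    seed: int
    survival_preset: str
    demography_shape: str
    software_version: str
    outputs: tuple[str, ...]

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config_path: str | Path) -> RunManifest:
    """Execute the experiments a config requests and write outputs + manifest."""
    config_path = Path(config_path)
    cfg = load_config(config_path)
    cfg_hash = hashlib.sha256(config_path.read_bytes()).hexdigest()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("run config %s (sha256 %s), seed %d", config_path, cfg_hash, cfg.seed)

    inputs = build_inputs(cfg)
    scenario = build_scenario(cfg, inputs.params)
    outputs: list[str] = []

    for exp in cfg.experiments:
        if exp == "base-case":
            res = run_base_case(
                inputs,
                scenario,
                stage_restricted_to=("C", "D") if cfg.campaign.stage_restricted else None,
            )
            path = out_dir / "base_case.csv"
            res.summary_frame().to_csv(path, index=False)
            _write_json(out_dir / "base_case.json", res.ce.as_dict())
            outputs += [str(path), str(out_dir / "base_case.json")]
        elif exp == "grid":
            grid = run_sensitivity_grid(
                inputs,
                durations=cfg.grid_durations,
                magnitudes=cfg.grid_magnitudes,
                stage_restricted=cfg.campaign.stage_restricted,
            )
            path = out_dir / "sensitivity_grid.csv"
            grid.table.to_csv(path, index=False)
            outputs.append(str(path))
        elif exp == "psa":
            psa = run_psa(
                inputs,
                scenario,
                n_samples=cfg.psa.n_samples,
                seed=cfg.seed,
                rel_se=cfg.psa.rel_se,
            )
            path = out_dir / "psa_samples.csv"
            psa.samples.to_csv(path, index=False)
            _write_json(
                out_dir / "psa_intervals.json",
                {k: list(v) for k, v in psa.intervals().items()},
            )
            outputs += [str(path), str(out_dir / "psa_intervals.json")]
        elif exp == "uptake-equivalence":
            target = cfg.uptake_target_qaly_gain
            if target is None:
                target = run_base_case(inputs, scenario).ce.delta_qaly
            res = screening_uptake_equivalence(inputs, target)
            path = out_dir / "uptake_equivalence.json"
            _write_json(path, res)
            outputs.append(str(path))
        elif exp == "pilot-stats":
            series = simulate_pilot(cfg)
            tests = pooled_and_regional_tests(series, cfg.pilot.step_month_index)
            path = out_dir / "pilot_stats.json"
            _write_json(
                path,
                {name: vars(result) for name, result in tests.items()},
            )
            outputs.append(str(path))
    manifest = RunManifest(
        config_hash=cfg_hash,
        seed=cfg.seed,
        survival_preset=cfg.survival_preset,
        demography_shape=cfg.demography.shape,
        software_version=__version__,
        outputs=tuple(outputs),
    )
    manifest.write(out_dir / "manifest.json")
    return manifest


def simulate_pilot(cfg: RunConfig) -> PilotSeries:
    """Generate the synthetic pilot series a config describes."""
    spec = PilotSeriesSpec(
        n_months=cfg.pilot.n_months,
        baseline_mean=cfg.pilot.baseline_means,
        step_month_index=cfg.pilot.step_month_index,
        step_multiplier=cfg.pilot.step_multiplier,
        seed=cfg.seed,
        regions=tuple(cfg.pilot.regions) if cfg.pilot.regions else None,
    )
    return generate_pilot_incidence_series(spec)
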