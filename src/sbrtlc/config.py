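"""Run configuration: model parameter blocks, scenario/scheme grids,
simulation settings, and the end-to-end pipeline driver.

An empty configuration file reproduces the published parameterization of
every model (α/β = 10 Gy; Martel D50 = 72.0 Gy, γ50 = 2.0; Ohri c = 10
Gy/cm, TCD50 = 0 Gy, k = 31 Gy; Guckenberger TCD50 = −1 Gy, k = 80 Gy;
Santiago TCD50 = −60.2 Gy, k = 113.3 Gy).  The Tai model ships disabled:
its published "Model Fit II" coefficients are not redistributed here, and
the built-in placeholder family must be explicitly acknowledged
(``tai.allow_placeholder: true``) before it contributes to reports.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .cohort import (
    cohort_from_csv,
    cohort_to_csv,
    impute_diameters,
    load_table1_fixture,
    plans_to_csv,
    simulate_cohort,
    simulate_plans,
)
from .lq import FractionScheme, RadiobiologyParams, scenario_from_name
from .models import LogisticTcpParams, MartelParams, ModelLibrary, OhriParams, TaiParams
from .pipeline import build_report, compute_lc_matrix, render_text_table

__all__ = ["RunConfig", "ConfigurationError", "load_config", "save_config", "run_pipeline"]


class ConfigurationError(ValueError):
    """Invalid or incomplete run configuration."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_default=True)


class RadiobiologyConfig(_Block):
    alpha_beta: float = Field(10.0, gt=0, description="LQ α/β ratio in Gy")


class MartelConfig(_Block):
    d50: float = Field(72.0, gt=0)
    gamma50: float = Field(2.0, gt=0)
    form: Literal["logit-power", "exponential-logistic"] = "logit-power"
    dose_input: Literal["isocenter", "prescription"] = "isocenter"


class OhriConfig(_Block):
    c: float = Field(10.0, ge=0, description="size penalty, Gy per cm")
    tcd50: float = 0.0
    k: float = Field(31.0, gt=0)


class LogisticModelConfig(_Block):
    tcd50: float
    k: float = Field(gt=0)


class TaiUserParams(_Block):
    """User-supplied regrowth dose-response coefficients (e.g. the Tai et
    al. multi-institutional 'Model Fit II' values, not bundled here)."""

    k: float = Field(gt=0)
    tcd50_2y: float
    tcd50_3y: float


class TaiConfig(_Block):
    enabled: bool = False
    allow_placeholder: bool = False
    params: Optional[TaiUserParams] = None

    @model_validator(mode="after")
    def _check_provenance(self) -> "TaiConfig":
        if self.enabled and self.params is None and not self.allow_placeholder:
            raise ValueError(
                "tai.enabled requires either tai.params (the published Tai et "
                "al. 'Model Fit II' coefficients) or tai.allow_placeholder: "
                "true to acknowledge use of the synthetic placeholder family"
            )
        return self


class SimulationConfig(_Block):
    n: int = Field(17, ge=0)
    seed: int = 0
    jitter: float = Field(0.02, ge=0, description="half-width of uniform Dmax-factor scatter")
    diameter_mean: float = Field(2.5, gt=0)
    diameter_sd: float = Field(0.9, ge=0)
    diameter_floor: float = Field(0.5, gt=0)
    t2_fraction: float = Field(3.0 / 17.0, ge=0, le=1)


class ReportConfig(_Block):
    zero_policy: Literal["drop", "pratt"] = "drop"
    alpha: float = Field(0.05, gt=0, lt=1)


class RunConfig(_Block):
    radiobiology: RadiobiologyConfig = Field(default_factory=RadiobiologyConfig)
    martel: MartelConfig = Field(default_factory=MartelConfig)
    ohri: OhriConfig = Field(default_factory=OhriConfig)
    gucken: LogisticModelConfig = Field(
        default_factory=lambda: LogisticModelConfig(tcd50=-1.0, k=80.0)
    )
    santiago: LogisticModelConfig = Field(
        default_factory=lambda: LogisticModelConfig(tcd50=-60.2, k=113.3)
    )
    tai: TaiConfig = Field(default_factory=TaiConfig)
    schemes: list[str] = Field(
        default_factory=lambda: ["1x30", "3x15", "4x12", "3x18", "5x10"]
    )
    scenarios: list[str] = Field(default_factory=lambda: ["P110", "P120"])
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    report: ReportConfig = Field(default_factory=ReportConfig)

    def build_library(self) -> ModelLibrary:
        if self.tai.params is not None:
            tai = TaiParams(
                k=self.tai.params.k,
                tcd50_by_horizon={2: self.tai.params.tcd50_2y, 3: self.tai.params.tcd50_3y},
                placeholder=False,
            )
        else:
            tai = TaiParams()
        return ModelLibrary(
            radiobiology=RadiobiologyParams(alpha_beta=self.radiobiology.alpha_beta),
            martel=MartelParams(
                d50=self.martel.d50, gamma50=self.martel.gamma50, form=self.martel.form
            ),
            ohri=OhriParams(
                logistic=LogisticTcpParams(tcd50=self.ohri.tcd50, k=self.ohri.k),
                c=self.ohri.c,
            ),
            gucken=LogisticTcpParams(tcd50=self.gucken.tcd50, k=self.gucken.k),
            santiago=LogisticTcpParams(tcd50=self.santiago.tcd50, k=self.santiago.k),
            tai=tai,
        )

    def build_roster(self) -> list[str]:
        roster = ["Martel", "Ohri", "Gucken", "Santiago"]
        if self.tai.enabled:
            roster.extend(["Tai2y", "Tai3y"])
        return roster

    def scheme_objects(self) -> list[FractionScheme]:
        return [FractionScheme.from_string(s) for s in self.schemes]


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML configuration; an empty or missing-keys
    file yields the all-defaults (published-parameter) configuration.
    Unknown keys are rejected with a message naming the key."""
    if path is None:
        return RunConfig()
    raw = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(raw)
    if data is None:
        data = {}
    try:
        return RunConfig.model_validate(data)
    except Exception as exc:  # pydantic's message already names the key
        raise ConfigurationError(str(exc)) from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(), sort_keys=True), encoding="utf-8"
    )


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    cohort_source: str | Path = "fixture",
) -> dict:
    """Execute the full comparison and write all artifacts to ``out_dir``.

    ``cohort_source`` is "fixture" (bundled 17-patient cohort with seeded
    synthetic diameters), "simulate" (fully synthetic cohort of
    ``simulation.n`` patients), or a cohort CSV path.  Deterministic given
    the configured seed: two runs produce byte-identical files.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation

    source = str(cohort_source)
    if source == "fixture":
        cohort = impute_diameters(
            load_table1_fixture(),
            seed=sim.seed,
            mean=sim.diameter_mean,
            sd=sim.diameter_sd,
            floor=sim.diameter_floor,
        )
    elif source == "simulate":
        cohort = simulate_cohort(
            sim.n,
            seed=sim.seed,
            diameter_mean=sim.diameter_mean,
            diameter_sd=sim.diameter_sd,
            t2_fraction=sim.t2_fraction,
            diameter_floor=sim.diameter_floor,
        )
    else:
        cohort = cohort_from_csv(cohort_source)

    schemes = config.scheme_objects()
    plans = []
    for i, scenario_name in enumerate(config.scenarios):
        scenario = scenario_from_name(scenario_name)
        plans.extend(
            simulate_plans(
                cohort,
                schemes,
                scenario,
                jitter_halfwidth=sim.jitter,
                seed=sim.seed + 1000003 * (i + 1),  # distinct stream per scenario
            )
        )

    library = config.build_library()
    matrix = compute_lc_matrix(cohort, plans, config.build_roster(), library)
    reports = build_report(
        matrix,
        alpha=config.report.alpha,
        zero_policy=config.report.zero_policy,
    )

    cohort_to_csv(cohort, out / "cohort.csv")
    plans_to_csv(plans, out / "plans.csv")
    matrix.frame.to_csv(out / "lc_matrix.csv", index=False, float_format="%.17g")
    written = ["cohort.csv", "plans.csv", "lc_matrix.csv"]
    from .pipeline import DEFAULT_BENCHMARKS

    for horizon, report in reports.items():
        report.to_csv(out / f"report_{horizon}y.csv", index=False, float_format="%.17g")
        (out / f"report_{horizon}y.txt").write_text(
            render_text_table(report, DEFAULT_BENCHMARKS[horizon]), encoding="utf-8"
        )
        written.extend([f"report_{horizon}y.csv", f"report_{horizon}y.txt"])

    manifest = {
        "package": "sbrtlc",
        "version": __version__,
        "cohort_source": source,
        "seed": sim.seed,
        "config": config.model_dump(),
        "outputs": written,
        "n_patients": len(cohort),
        "n_plans": len(plans),
        "synthetic_diameters": source in ("fixture", "simulate"),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
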