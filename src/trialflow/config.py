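"""Declarative YAML run configuration.

A run is described by a single YAML document validated into
:class:`RunConfig` (pydantic, unknown keys rejected, errors reported with
field paths).  An empty document yields the full default configuration:
the four canonical scenarios, the reference cost model and the default
PSA specification.  ``RunConfig`` round-trips losslessly through
:func:`save_config` / :func:`load_config`.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import psa as _psa
from .design import StageDesign
from .economics import CostModel
from .flow import Scenario

__all__ = [
    "StageConfig",
    "ScenarioConfig",
    "CostConfig",
    "DistConfig",
    "PsaConfig",
    "RunConfig",
    "load_config",
    "save_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StageConfig(_Strict):
    alpha: float = Field(gt=0, lt=1)
    power: float = Field(gt=0, lt=1)
    n_trials: int = Field(1, ge=1)
    sidedness: Literal["one-sided", "two-sided"] = "two-sided"

    def to_design(self) -> StageDesign:
        return StageDesign(self.alpha, self.power, self.n_trials, self.sidedness)


def _phase3_default() -> StageConfig:
    return StageConfig(alpha=0.05, power=0.90, n_trials=2)


class ScenarioConfig(_Strict):
    name: str
    phase2: StageConfig
    phase3: StageConfig = Field(default_factory=_phase3_default)

    def to_scenario(self, p_eff: float, n_candidates: float) -> Scenario:
        return Scenario(
            self.name, self.phase2.to_design(), self.phase3.to_design(), p_eff, n_candidates
        )


class CostConfig(_Strict):
    phase2_cost_reference: float = Field(40.0, ge=0)
    phase3_cost_per_treatment: float = Field(163.0, ge=0)
    cost_per_participant: float = Field(200_000.0, ge=0)
    reference_cost_per_participant: float = Field(200_000.0, gt=0)
    economies_factor: float = Field(1.0, gt=0, le=1)
    return_per_success: float = Field(2_500.0, ge=0)
    phase2_effect_multiplier: float = Field(1.0, ge=1)
    z_rounding: Literal["none", "two_decimals"] = "two_decimals"

    def to_cost_model(self) -> CostModel:
        return CostModel(
            phase2_cost_reference=self.phase2_cost_reference,
            phase3_cost_per_treatment=self.phase3_cost_per_treatment,
            cost_per_participant=self.cost_per_participant,
            reference_cost_per_participant=self.reference_cost_per_participant,
            economies_factor=self.economies_factor,
            return_per_success=self.return_per_success,
            phase2_effect_multiplier=self.phase2_effect_multiplier,
            z_rounding=self.z_rounding,
        )


class DistConfig(_Strict):
    """One named input distribution; required fields depend on ``kind``."""

    kind: Literal["point", "truncnorm", "uniform", "beta", "lognormal_cv"]
    value: Optional[float] = None
    mu: Optional[float] = None
    sd: Optional[float] = None
    lower: Optional[float] = None
    low: Optional[float] = None
    high: Optional[float] = None
    a: Optional[float] = None
    b: Optional[float] = None
    median: Optional[float] = None
    cv: Optional[float] = None

    _REQUIRED = {
        "point": ("value",),
        "truncnorm": ("mu", "sd"),
        "uniform": ("low", "high"),
        "beta": ("a", "b"),
        "lognormal_cv": ("median", "cv"),
    }
    _ALLOWED = {
        "point": ("value",),
        "truncnorm": ("mu", "sd", "lower"),
        "uniform": ("low", "high"),
        "beta": ("a", "b"),
        "lognormal_cv": ("median", "cv"),
    }

    @model_validator(mode="after")
    def _check_fields(self) -> "DistConfig":
        fields = (
            "value", "mu", "sd", "lower", "low", "high", "a", "b", "median", "cv",
        )
        given = {f for f in fields if getattr(self, f) is not None}
        required = set(self._REQUIRED[self.kind])
        allowed = set(self._ALLOWED[self.kind])
        if missing := required - given:
            raise ValueError(f"{self.kind} distribution requires {sorted(missing)}")
        if stray := given - allowed:
            raise ValueError(f"{self.kind} distribution does not accept {sorted(stray)}")
        return self

    def to_distribution(self) -> _psa.Distribution:
        if self.kind == "point":
            return _psa.PointMass(self.value)  # type: ignore[arg-type]
        if self.kind == "truncnorm":
            lower = self.lower if self.lower is not None else float("-inf")
            return _psa.TruncatedNormal(self.mu, self.sd, lower)  # type: ignore[arg-type]
        if self.kind == "uniform":
            return _psa.Uniform(self.low, self.high)  # type: ignore[arg-type]
        if self.kind == "beta":
            return _psa.Beta(self.a, self.b)  # type: ignore[arg-type]
        return _psa.LogNormalMedianCV(self.median, self.cv)  # type: ignore[arg-type]


def _d_effect() -> DistConfig:
    return DistConfig(kind="truncnorm", mu=1.0, sd=0.15, lower=0.5)


def _d_p_eff() -> DistConfig:
    return DistConfig(kind="beta", a=5.0, b=15.0)


def _d_cpp() -> DistConfig:
    return DistConfig(kind="uniform", low=100_000.0, high=400_000.0)


def _d_return() -> DistConfig:
    return DistConfig(kind="lognormal_cv", median=2_500.0, cv=0.5)


class PsaConfig(_Strict):
    enabled: bool = True
    n_samples: int = Field(10_000, ge=1)
    portfolio_size: int = Field(100, ge=1)
    portfolio_sampling: bool = False
    effect_multiplier: DistConfig = Field(default_factory=_d_effect)
    p_eff: DistConfig = Field(default_factory=_d_p_eff)
    cost_per_participant: DistConfig = Field(default_factory=_d_cpp)
    return_per_success: DistConfig = Field(default_factory=_d_return)


def _default_scenarios() -> List[ScenarioConfig]:
    return [
        ScenarioConfig(name="Scenario 1", phase2=StageConfig(alpha=0.05, power=0.50)),
        ScenarioConfig(name="Scenario 2", phase2=StageConfig(alpha=0.05, power=0.80)),
        ScenarioConfig(name="Scenario 3", phase2=StageConfig(alpha=0.01, power=0.50)),
        ScenarioConfig(name="Scenario 4", phase2=StageConfig(alpha=0.20, power=0.95)),
    ]


class RunConfig(_Strict):
    """Complete, validated description of a simulator run."""

    scenarios: List[ScenarioConfig] = Field(default_factory=_default_scenarios)
    p_eff: float = Field(0.25, ge=0, le=1)
    n_candidates: float = Field(100, gt=0)
    cost: CostConfig = Field(default_factory=CostConfig)
    psa: PsaConfig = Field(default_factory=PsaConfig)
    seed: int = 0
    rounding: Literal["exact", "printed"] = "printed"

    def to_scenarios(self) -> List[Scenario]:
        return [s.to_scenario(self.p_eff, self.n_candidates) for s in self.scenarios]

    def to_cost_model(self) -> CostModel:
        return self.cost.to_cost_model()

    def to_psa_spec(self) -> _psa.PsaSpec:
        return _psa.PsaSpec(
            n_samples=self.psa.n_samples,
            portfolio_size=self.psa.portfolio_size,
            seed=self.seed,
            effect_multiplier=self.psa.effect_multiplier.to_distribution(),
            p_eff=self.psa.p_eff.to_distribution(),
            cost_per_participant=self.psa.cost_per_participant.to_distribution(),
            return_per_success=self.psa.return_per_success.to_distribution(),
            scenarios=tuple(self.to_scenarios()),
            cost_model=self.to_cost_model(),
            portfolio_sampling=self.psa.portfolio_sampling,
        )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Read and validate a YAML config; ``None`` or empty file = defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    return RunConfig.model_validate(raw if raw is not None else {})


def save_config(config: RunConfig, path: str | Path) -> None:
    """Serialize a config so that ``load_config`` restores it exactly."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
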