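"""Probabilistic sensitivity analysis and stochastic portfolio simulation.

``run_psa`` samples the uncertain inputs — a multiplier on the true effect
size, the proportion of effective candidates, the cost per participant
and the return on a success — and pushes each draw through the pipeline
and economic layers for every scenario, holding the scenarios' alpha/beta
thresholds fixed.  With ``portfolio_sampling`` off, each draw uses the
expected-count flow (classic PSA: parameter uncertainty only, so
point-mass inputs collapse exactly to the deterministic result).  With it
on, each draw additionally realizes a finite portfolio of candidates via
binomial pass/fail sampling (first-order, finite-cohort noise).

The effect-size multiplier ``m`` rescales the required sample size, and
hence both phase program costs, by ``1/m^2`` (power is held at its nominal
level, so a smaller true effect must be bought with more participants).

Scenario comparisons are paired: every scenario sees the same input draws
(common random numbers at the parameter level), and portfolio noise uses
deterministic per-scenario child streams of the root seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .economics import CostModel
from .design import sample_size_ratio
from .flow import FlowResult, Scenario
from .scenarios import default_scenarios

__all__ = [
    "Distribution",
    "PointMass",
    "TruncatedNormal",
    "Uniform",
    "Beta",
    "LogNormalMedianCV",
    "PsaSpec",
    "PsaResult",
    "sample_inputs",
    "simulate_portfolio",
    "run_psa",
    "correlate_profit_differences",
]

INPUT_COLUMNS = ("effect_multiplier", "p_eff", "cost_per_participant", "return_per_success")


# ---------------------------------------------------------------------------
# input distributions
# ---------------------------------------------------------------------------
class Distribution:
    """Interface: a named sampling distribution for one uncertain input."""

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        raise NotImplementedError

    def mean(self) -> float:
        raise NotImplementedError

    def support(self) -> Tuple[float, float]:
        raise NotImplementedError


@dataclass(frozen=True)
class PointMass(Distribution):
    value: float

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.full(size, self.value)

    def mean(self) -> float:
        return self.value

    def support(self) -> Tuple[float, float]:
        return (self.value, self.value)


@dataclass(frozen=True)
class TruncatedNormal(Distribution):
    """Normal(mu, sd) truncated below at ``lower``."""

    mu: float
    sd: float
    lower: float = -math.inf

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    def _frozen(self):
        a = (self.lower - self.mu) / self.sd
        return stats.truncnorm(a, math.inf, loc=self.mu, scale=self.sd)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self._frozen().rvs(size=size, random_state=rng)

    def mean(self) -> float:
        return float(self._frozen().mean())

    def support(self) -> Tuple[float, float]:
        return (self.lower, math.inf)


@dataclass(frozen=True)
class Uniform(Distribution):
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("require low < high")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.uniform(self.low, self.high, size)

    def mean(self) -> float:
        return 0.5 * (self.low + self.high)

    def support(self) -> Tuple[float, float]:
        return (self.low, self.high)


@dataclass(frozen=True)
class Beta(Distribution):
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("shape parameters must be positive")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.beta(self.a, self.b, size)

    def mean(self) -> float:
        return self.a / (self.a + self.b)

    def support(self) -> Tuple[float, float]:
        return (0.0, 1.0)


@dataclass(frozen=True)
class LogNormalMedianCV(Distribution):
    """Log-normal parameterized by its median and coefficient of variation."""

    median: float
    cv: float

    def __post_init__(self) -> None:
        if self.median <= 0 or self.cv <= 0:
            raise ValueError("median and cv must be positive")

    @property
    def _sigma(self) -> float:
        return math.sqrt(math.log1p(self.cv**2))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.lognormal(math.log(self.median), self._sigma, size)

    def mean(self) -> float:
        return self.median * math.sqrt(1.0 + self.cv**2)

    def support(self) -> Tuple[float, float]:
        return (0.0, math.inf)


# ---------------------------------------------------------------------------
# specification and result containers
# ---------------------------------------------------------------------------
def _default_effect() -> Distribution:
    return TruncatedNormal(1.0, 0.15, lower=0.5)


def _default_p_eff() -> Distribution:
    return Beta(5.0, 15.0)  # mean 0.25


def _default_cpp() -> Distribution:
    return Uniform(100_000.0, 400_000.0)


def _default_return() -> Distribution:
    return LogNormalMedianCV(2_500.0, 0.5)


@dataclass(frozen=True)
class PsaSpec:
    """Monte Carlo sampling specification.

    Defaults: 10,000 samples of portfolios of 100 candidates over the four
    canonical scenarios, with dispersed priors on effect-size multiplier,
    effective proportion, participant cost and return on success.
    """

    n_samples: int = 10_000
    portfolio_size: int = 100
    seed: int = 0
    effect_multiplier: Distribution = field(default_factory=_default_effect)
    p_eff: Distribution = field(default_factory=_default_p_eff)
    cost_per_participant: Distribution = field(default_factory=_default_cpp)
    return_per_success: Distribution = field(default_factory=_default_return)
    scenarios: Tuple[Scenario, ...] = field(default_factory=default_scenarios)
    cost_model: CostModel = field(default_factory=CostModel)
    portfolio_sampling: bool = False

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.portfolio_size < 1:
            raise ValueError("portfolio_size must be >= 1")
        if len(self.scenarios) == 0:
            raise ValueError("at least one scenario is required")
        lo, hi = self.p_eff.support()
        if lo < 0.0 or hi > 1.0:
            raise ValueError("p_eff distribution support must lie within [0, 1]")
        for name in ("effect_multiplier", "cost_per_participant", "return_per_success"):
            if getattr(self, name).support()[0] < 0.0:
                raise ValueError(f"{name} distribution support must be nonnegative")


@dataclass(frozen=True)
class PsaResult:
    """Output of :func:`run_psa`.

    ``draws`` holds the sampled inputs (one row per Monte Carlo sample);
    ``profits`` one profit column per scenario ($M); ``summary`` the
    per-scenario mean and 2.5/97.5 percentiles; ``differences`` the paired
    profit differences of each scenario against the baseline (the first
    scenario of the spec); ``correlations`` the rank correlation of each
    difference with each sampled input.
    """

    spec: PsaSpec
    draws: pd.DataFrame
    profits: pd.DataFrame
    summary: pd.DataFrame
    differences: pd.DataFrame
    correlations: pd.DataFrame

    @property
    def baseline(self) -> str:
        return self.spec.scenarios[0].name


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------
def _streams(spec: PsaSpec):
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(1 + len(spec.scenarios))
    return (
        np.random.default_rng(children[0]),
        [np.random.default_rng(c) for c in children[1:]],
    )


def sample_inputs(spec: PsaSpec) -> pd.DataFrame:
    """Jointly independent input draws, reproducible from the spec's seed."""
    rng, _ = _streams(spec)
    n = spec.n_samples
    return pd.DataFrame(
        {
            "effect_multiplier": spec.effect_multiplier.sample(rng, n),
            "p_eff": spec.p_eff.sample(rng, n),
            "cost_per_participant": spec.cost_per_participant.sample(rng, n),
            "return_per_success": spec.return_per_success.sample(rng, n),
        }
    )


def simulate_portfolio(
    draw: Dict[str, float] | pd.Series,
    scenario: Scenario,
    rng: np.random.Generator,
    portfolio_size: int = 100,
    method: str = "binomial",
) -> FlowResult:
    """One realized (integer-count) portfolio under a sampled parameter draw.

    The number of effective candidates is Binomial(portfolio_size, p_eff);
    per-stage passes are binomial with the class-appropriate composite
    probabilities.  ``method="per_candidate"`` draws individual Bernoulli
    candidates instead (slower; for debugging/validation).
    """
    p_eff = float(draw["p_eff"]) if "p_eff" in draw else scenario.p_eff
    pw2, a2 = scenario.phase2.power_composite, scenario.phase2.alpha_composite
    pw3, a3 = scenario.phase3.power_composite, scenario.phase3.alpha_composite
    if method == "binomial":
        n_eff = int(rng.binomial(portfolio_size, p_eff))
        e2 = int(rng.binomial(n_eff, pw2))
        e3 = int(rng.binomial(e2, pw3))
        n_ineff = portfolio_size - n_eff
        i2 = int(rng.binomial(n_ineff, a2))
        i3 = int(rng.binomial(i2, a3))
    elif method == "per_candidate":
        eff = rng.random(portfolio_size) < p_eff
        n_eff = int(eff.sum())
        n_ineff = portfolio_size - n_eff
        pass2 = np.where(eff, rng.random(portfolio_size) < pw2, rng.random(portfolio_size) < a2)
        pass3 = pass2 & np.where(
            eff, rng.random(portfolio_size) < pw3, rng.random(portfolio_size) < a3
        )
        e2 = int((eff & pass2).sum())
        e3 = int((eff & pass3).sum())
        i2 = int((~eff & pass2).sum())
        i3 = int((~eff & pass3).sum())
    else:
        raise ValueError(f"unknown method {method!r}")
    return FlowResult(
        scenario=scenario,
        eff_enter=n_eff,
        eff_pass2=e2,
        eff_pass3=e3,
        ineff_enter=n_ineff,
        ineff_pass2=i2,
        ineff_pass3=i3,
    )


def _profit_draws(
    scenario: Scenario,
    draws: pd.DataFrame,
    spec: PsaSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized profit per Monte Carlo sample for one scenario."""
    cm = spec.cost_model
    n = spec.portfolio_size
    m = draws["effect_multiplier"].to_numpy()
    p_eff = draws["p_eff"].to_numpy()
    cpp = draws["cost_per_participant"].to_numpy()
    ret = draws["return_per_success"].to_numpy()

    pw2, a2 = scenario.phase2.power_composite, scenario.phase2.alpha_composite
    pw3, a3 = scenario.phase3.power_composite, scenario.phase3.alpha_composite

    if spec.portfolio_sampling:
        n_eff = rng.binomial(n, p_eff)
        e2 = rng.binomial(n_eff, pw2)
        e3 = rng.binomial(e2, pw3)
        i2 = rng.binomial(n - n_eff, a2)
        i3 = rng.binomial(i2, a3)
    else:
        n_eff = n * p_eff
        e2 = n_eff * pw2
        e3 = e2 * pw3
        i2 = (n - n_eff) * a2
        i3 = i2 * a3

    entrants3 = e2 + i2
    passers = e3 + i3

    ratio0 = sample_size_ratio(scenario.phase2, cm.reference_design, cm.z_rounding)
    ratio = ratio0 / m**2
    mult = np.where(
        ratio > 1.0, 1.0 + cm.economies_factor * (ratio - 1.0), ratio
    )
    unit = cpp / cm.reference_cost_per_participant
    cost2 = n * cm.phase2_cost_reference * unit * mult
    cost3 = entrants3 * cm.phase3_cost_per_treatment * unit / m**2
    return ret * passers - cost2 - cost3


def run_psa(spec: PsaSpec) -> PsaResult:
    """Full PSA: sample inputs, run flow + economics per scenario, summarize."""
    input_rng, scen_rngs = _streams(spec)
    del input_rng  # sample_inputs re-derives the same stream from the spec
    draws = sample_inputs(spec)

    profits = pd.DataFrame(
        {
            scen.name: _profit_draws(scen, draws, spec, rng)
            for scen, rng in zip(spec.scenarios, scen_rngs)
        }
    )

    summary = pd.DataFrame(
        {
            "mean": profits.mean(),
            "sd": profits.std(ddof=1),
            "p2.5": profits.quantile(0.025),
            "p97.5": profits.quantile(0.975),
        }
    )
    summary.index.name = "scenario"

    base = spec.scenarios[0].name
    differences = pd.DataFrame(
        {
            f"{scen.name} - {base}": profits[scen.name] - profits[base]
            for scen in spec.scenarios[1:]
        }
    )

    result = PsaResult(
        spec=spec,
        draws=draws,
        profits=profits,
        summary=summary,
        differences=differences,
        correlations=pd.DataFrame(),
    )
    correlations = correlate_profit_differences(result)
    return PsaResult(
        spec=spec,
        draws=draws,
        profits=profits,
        summary=summary,
        differences=differences,
        correlations=correlations,
    )


def correlate_profit_differences(
    result: PsaResult, extra_inputs: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Spearman rank correlation of paired profit differences with inputs.

    One row per scenario-vs-baseline difference, one column per sampled
    input.  Degenerate (constant) columns yield NaN — reported, not raised.
    Rank correlation is used because several inputs are skewed.
    ``extra_inputs`` allows appending control columns (e.g. a dummy input
    for a null check).
    """
    inputs = result.draws
    if extra_inputs is not None:
        inputs = pd.concat([inputs, extra_inputs], axis=1)
    rows = {}
    for diff_name in result.differences.columns:
        diff = result.differences[diff_name].to_numpy()
        row = {}
        for col in inputs.columns:
            x = inputs[col].to_numpy()
            if np.all(diff == diff[0]) or np.all(x == x[0]):
                row[col] = math.nan
            else:
                rho = stats.spearmanr(x, diff).statistic
                row[col] = float(rho)
        rows[diff_name] = row
    return pd.DataFrame.from_dict(rows, orient="index")
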