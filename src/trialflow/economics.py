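"""Monetary layer: program costs, expected returns and profit.

Phase II costs scale with the sample-size ratio of the scenario's phase II
design relative to the reference design (alpha 5% two-sided, power 50% —
the $40M, 200-participant program).  An economies-of-scale factor can
discount the *incremental* part of that scaling.  Phase III costs are a
fixed amount per treatment entering phase III (the phase III design never
changes across scenarios).  Returns accrue per treatment passing phase III
regardless of class, using exact (unrounded) expected counts.

All amounts are in millions of dollars except ``cost_per_participant``,
which is in dollars and rescales both program costs relative to the
$200,000 reference (40 $M = 200,000 $ x 200 participants).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

from .design import StageDesign, ZRounding, sample_size_ratio
from .flow import FlowResult, Mode, Scenario, productivity_metrics, run_flow
from .rounding import round1

__all__ = [
    "CostModel",
    "EconomicResult",
    "ScenarioResult",
    "phase2_program_cost",
    "phase3_program_cost",
    "expected_return",
    "profit",
    "evaluate_scenario",
    "compare_scenarios",
]


def _reference_phase2() -> StageDesign:
    return StageDesign(0.05, 0.50, n_trials=1)


@dataclass(frozen=True)
class CostModel:
    """Monetary parameters of the development economics.

    Parameters
    ----------
    phase2_cost_reference : float
        $M per treatment for a phase II study at the reference design.
    phase3_cost_per_treatment : float
        $M per treatment entering phase III.
    cost_per_participant : float
        Dollars per study participant; scales both program costs relative
        to ``reference_cost_per_participant``.
    economies_factor : float
        In (0, 1]; applied to the incremental part of the phase II
        sample-size scaling (1.0 = no economies of scale, 0.8 = a 20%
        discount on the extra participants).
    return_per_success : float
        $M earned per treatment passing phase III.
    phase2_effect_multiplier : float
        >= 1; the "adjusted" analyses assume a larger effect size at
        phase II (surrogate endpoints / enriched samples), shrinking the
        required phase II sample size — and hence cost — by its square.
    z_rounding : {"two_decimals", "none"}
        Quantile rounding used in the sample-size ratio.  Two-decimal
        quantiles (1.96, 0.84) are the default; they reproduce published
        program-cost ratios.
    """

    phase2_cost_reference: float = 40.0
    phase3_cost_per_treatment: float = 163.0
    cost_per_participant: float = 200_000.0
    reference_cost_per_participant: float = 200_000.0
    economies_factor: float = 1.0
    return_per_success: float = 2_500.0
    phase2_effect_multiplier: float = 1.0
    z_rounding: ZRounding = "two_decimals"
    reference_design: StageDesign = field(default_factory=_reference_phase2)

    def __post_init__(self) -> None:
        for name in (
            "phase2_cost_reference",
            "phase3_cost_per_treatment",
            "cost_per_participant",
            "reference_cost_per_participant",
            "return_per_success",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 < self.economies_factor <= 1.0:
            raise ValueError(f"economies_factor must be in (0, 1], got {self.economies_factor!r}")
        if self.phase2_effect_multiplier < 1.0:
            raise ValueError(
                f"phase2_effect_multiplier must be >= 1, got {self.phase2_effect_multiplier!r}"
            )

    @property
    def participant_cost_factor(self) -> float:
        return self.cost_per_participant / self.reference_cost_per_participant


@dataclass(frozen=True)
class EconomicResult:
    """Costs, expected return and profit of one scenario, in $M."""

    cost_phase2: float
    cost_phase3: float
    expected_return: float

    @property
    def total_cost(self) -> float:
        return self.cost_phase2 + self.cost_phase3

    @property
    def profit(self) -> float:
        return self.expected_return - self.total_cost


@dataclass(frozen=True)
class ScenarioResult:
    """A scenario bundled with its expected flow and economics."""

    scenario: Scenario
    flow: FlowResult
    economics: EconomicResult


def cost_multiplier(ratio: float, economies_factor: float) -> float:
    """Scale factor applied to the reference phase II cost.

    For a sample-size ratio above 1 only the incremental part is
    discounted: ``1 + economies_factor * (ratio - 1)``; a ratio below 1
    (smaller study) passes through untouched.
    """
    return 1.0 + economies_factor * (ratio - 1.0) if ratio > 1.0 else ratio


def phase2_program_cost(scenario: Scenario, cm: CostModel) -> float:
    """$M spent on phase II for the whole portfolio (all candidates tested)."""
    ratio = (
        sample_size_ratio(scenario.phase2, cm.reference_design, cm.z_rounding)
        / cm.phase2_effect_multiplier**2
    )
    return (
        scenario.n_candidates
        * cm.phase2_cost_reference
        * cm.participant_cost_factor
        * cost_multiplier(ratio, cm.economies_factor)
    )


def phase3_program_cost(flow: FlowResult, cm: CostModel) -> float:
    """$M spent on phase III: entrants times the per-treatment cost."""
    return flow.phase3_entrants * cm.phase3_cost_per_treatment * cm.participant_cost_factor


def expected_return(flow: FlowResult, cm: CostModel) -> float:
    """$M earned: every phase III passer (either class) returns the same."""
    return cm.return_per_success * flow.total_pass3


def profit(scenario: Scenario, flow: FlowResult, cm: CostModel) -> EconomicResult:
    """Assemble the economic result: profit = return - (phase II + III costs)."""
    return EconomicResult(
        cost_phase2=phase2_program_cost(scenario, cm),
        cost_phase3=phase3_program_cost(flow, cm),
        expected_return=expected_return(flow, cm),
    )


def evaluate_scenario(scenario: Scenario, cm: Optional[CostModel] = None) -> ScenarioResult:
    """Run the expected flow and the economic layer for one scenario."""
    cm = cm if cm is not None else CostModel()
    fl = run_flow(scenario)
    return ScenarioResult(scenario, fl, profit(scenario, fl, cm))


def _pct_change(a: float, b: float) -> float:
    """(a - b) / b in percent; NaN (not an exception) on a zero baseline."""
    if b == 0.0:
        return math.nan
    return 100.0 * (a - b) / b


def compare_scenarios(
    a: ScenarioResult, b: ScenarioResult, mode: Mode = "exact"
) -> Dict[str, float]:
    """Percent changes of a vs baseline b (productivity, costs, return, profit)."""
    sa, sb = a.scenario, b.scenario
    if (sa.n_candidates, sa.p_eff) != (sb.n_candidates, sb.p_eff):
        raise ValueError("scenarios under comparison must share the candidate mix")
    prod_a = productivity_metrics(a.flow, mode=mode).productivity_pct
    prod_b = productivity_metrics(b.flow, mode=mode).productivity_pct
    deltas = {
        "productivity": _pct_change(prod_a, prod_b),
        "cost_phase2": _pct_change(a.economics.cost_phase2, b.economics.cost_phase2),
        "cost_phase3": _pct_change(a.economics.cost_phase3, b.economics.cost_phase3),
        "expected_return": _pct_change(
            a.economics.expected_return, b.economics.expected_return
        ),
        "profit": _pct_change(a.economics.profit, b.economics.profit),
    }
    if mode == "printed":
        deltas = {k: (round1(v) if not math.isnan(v) else v) for k, v in deltas.items()}
    return deltas
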