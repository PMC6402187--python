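"""Exploration of the phase II design space and one-dimensional sweeps.

``profit_surface`` evaluates expected profit (and productivity) over a
grid of phase II (alpha, power) pairs with everything else fixed;
``find_optimum`` returns the most profitable cell.  The default grid uses
the alpha levels {1, 5, 10, 20, 30}% with power from 50% to 99% in 1%
steps, and a cost model with the 80% economies-of-scale correction — the
convention under which the grid optimum lands at alpha 20% / power 95%.

The sweep helpers trace profit against cost-per-participant and against
the effective-candidate proportion for a set of scenarios.  Sweeps scale
BOTH phase II and phase III program costs proportionally to the unit
participant cost (a global unit-cost perturbation), so profit tends to
the expected return as the cost per participant goes to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import StageDesign
from .economics import CostModel, evaluate_scenario
from .flow import Scenario, productivity_metrics
from .scenarios import scenario_1

__all__ = [
    "SearchGrid",
    "ProfitSurface",
    "default_search_grid",
    "profit_surface",
    "find_optimum",
    "sweep_cost_per_participant",
    "sweep_p_eff",
]

#: Alpha levels of the plotted profit-vs-power lines.
DEFAULT_ALPHA_VALUES: Tuple[float, ...] = (0.01, 0.05, 0.10, 0.20, 0.30)


def _default_powers() -> Tuple[float, ...]:
    return tuple(round(0.50 + 0.01 * i, 2) for i in range(50))


def _search_cost_model() -> CostModel:
    # stated economies-of-scale assumption; see docs/methods.md for why the
    # surface uses 0.8 while the tabulated economics default to 1.0
    return CostModel(economies_factor=0.8)


@dataclass(frozen=True)
class SearchGrid:
    """Axes of phase II (alpha, power) values plus the fixed context."""

    alpha_values: Tuple[float, ...] = DEFAULT_ALPHA_VALUES
    power_values: Tuple[float, ...] = field(default_factory=_default_powers)
    template: Scenario = field(default_factory=scenario_1)
    cost_model: CostModel = field(default_factory=_search_cost_model)

    def __post_init__(self) -> None:
        for name, axis in (("alpha_values", self.alpha_values), ("power_values", self.power_values)):
            if len(axis) == 0:
                raise ValueError(f"{name} must be nonempty")
            if any(not 0.0 < v < 1.0 for v in axis):
                raise ValueError(f"{name} must lie strictly in (0, 1)")
            if any(b <= a for a, b in zip(axis, axis[1:])):
                raise ValueError(f"{name} must be strictly increasing")


@dataclass(frozen=True)
class ProfitSurface:
    """Profit ($M) and productivity (%) over the (alpha, power) grid.

    ``profit[i, j]`` corresponds to ``alpha_values[i]``, ``power_values[j]``.
    """

    alpha_values: Tuple[float, ...]
    power_values: Tuple[float, ...]
    profit: np.ndarray
    productivity_pct: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (alpha, power) cell."""
        rows = [
            {
                "alpha": a,
                "power": p,
                "profit": float(self.profit[i, j]),
                "productivity_pct": float(self.productivity_pct[i, j]),
            }
            for i, a in enumerate(self.alpha_values)
            for j, p in enumerate(self.power_values)
        ]
        return pd.DataFrame(rows)


def default_search_grid() -> SearchGrid:
    return SearchGrid()


def profit_surface(grid: SearchGrid) -> ProfitSurface:
    """Expected profit and productivity at every grid cell."""
    na, np_ = len(grid.alpha_values), len(grid.power_values)
    prof = np.empty((na, np_))
    prod = np.empty((na, np_))
    t = grid.template
    for i, a in enumerate(grid.alpha_values):
        for j, p in enumerate(grid.power_values):
            scen = Scenario(
                name=f"alpha={a:g},power={p:g}",
                phase2=StageDesign(a, p, t.phase2.n_trials, t.phase2.sidedness),
                phase3=t.phase3,
                p_eff=t.p_eff,
                n_candidates=t.n_candidates,
            )
            res = evaluate_scenario(scen, grid.cost_model)
            prof[i, j] = res.economics.profit
            prod[i, j] = productivity_metrics(res.flow).productivity_pct
    return ProfitSurface(tuple(grid.alpha_values), tuple(grid.power_values), prof, prod)


def find_optimum(surface: ProfitSurface) -> Tuple[float, float, float]:
    """(alpha, power, profit) of the most profitable cell.

    Ties break deterministically toward the lowest alpha, then the lowest
    power (scan order with a strict improvement test).
    """
    if surface.profit.size == 0:
        raise ValueError("empty surface")
    best: Optional[Tuple[float, float, float]] = None
    for i, a in enumerate(surface.alpha_values):
        for j, p in enumerate(surface.power_values):
            v = float(surface.profit[i, j])
            if best is None or v > best[2]:
                best = (a, p, v)
    assert best is not None
    return best


def sweep_cost_per_participant(
    scenarios: Sequence[Scenario],
    cost_values: Sequence[float],
    cost_model: Optional[CostModel] = None,
    phase3_power_per_trial: Optional[float] = None,
) -> pd.DataFrame:
    """Profit vs cost-per-participant, one curve per scenario.

    ``phase3_power_per_trial`` optionally overrides the per-trial phase III
    power (e.g. 0.80 vs 0.90) while keeping two confirmatory trials.
    Returns a tidy frame (scenario, cost_per_participant, profit).
    """
    if any(c <= 0 for c in cost_values):
        raise ValueError("cost_per_participant values must be positive")
    cm = cost_model if cost_model is not None else _search_cost_model()
    rows = []
    for scen in scenarios:
        if phase3_power_per_trial is not None:
            scen = replace(
                scen,
                phase3=StageDesign(
                    scen.phase3.alpha_per_trial,
                    phase3_power_per_trial,
                    scen.phase3.n_trials,
                    scen.phase3.sidedness,
                ),
            )
        for c in cost_values:
            res = evaluate_scenario(scen, replace(cm, cost_per_participant=float(c)))
            rows.append(
                {
                    "scenario": scen.name,
                    "cost_per_participant": float(c),
                    "profit": res.economics.profit,
                }
            )
    return pd.DataFrame(rows)


def sweep_p_eff(
    scenarios: Sequence[Scenario],
    p_values: Sequence[float],
    cost_model: Optional[CostModel] = None,
) -> pd.DataFrame:
    """Profit vs proportion of effective candidates, one curve per scenario."""
    if any(not 0.0 <= p <= 1.0 for p in p_values):
        raise ValueError("p_eff values must lie in [0, 1]")
    cm = cost_model if cost_model is not None else _search_cost_model()
    rows = []
    for scen in scenarios:
        for p in p_values:
            res = evaluate_scenario(replace(scen, p_eff=float(p)), cm)
            rows.append(
                {"scenario": scen.name, "p_eff": float(p), "profit": res.economics.profit}
            )
    return pd.DataFrame(rows)
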