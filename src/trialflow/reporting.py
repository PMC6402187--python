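"""Table rendering and the batch run-everything entry point.

Tables come in two conventions: ``exact`` (full precision) and
``printed`` (counts rounded half-up to one decimal before derived
percentages — the published-table convention).  :func:`run_all` executes
flows, economics, the profit surface, both sweeps and (optionally) the
PSA for a validated :class:`~trialflow.config.RunConfig`, writing CSV/JSON
plus a metadata block recording every convention flag.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Sequence

import pandas as pd

from . import __version__
from .config import RunConfig
from .economics import ScenarioResult, compare_scenarios, evaluate_scenario
from .flow import FlowResult, Mode, productivity_metrics, run_flow
from .psa import run_psa
from .rounding import round1
from .search import (
    SearchGrid,
    find_optimum,
    profit_surface,
    sweep_cost_per_participant,
    sweep_p_eff,
)

__all__ = ["flow_table", "render_flow_table", "summary_table", "run_all"]


def flow_table(flows: Sequence[FlowResult], mode: Mode = "printed") -> pd.DataFrame:
    """Tidy per-stage counts: one row per (scenario, class, stage)."""
    if len(flows) == 0:
        raise ValueError("at least one flow is required")
    fmt = round1 if mode == "printed" else float
    rows = []
    for f in flows:
        for cls, enter, p2, p3 in (
            ("effective", f.eff_enter, f.eff_pass2, f.eff_pass3),
            ("ineffective", f.ineff_enter, f.ineff_pass2, f.ineff_pass3),
        ):
            rows.append(
                {
                    "scenario": f.scenario.name,
                    "class": cls,
                    "stage": "phase II",
                    "enter": fmt(enter),
                    "pass": fmt(p2),
                    "fail": fmt(enter - p2),
                }
            )
            rows.append(
                {
                    "scenario": f.scenario.name,
                    "class": cls,
                    "stage": "phase III",
                    "enter": fmt(p2),
                    "pass": fmt(p3),
                    "fail": fmt(p2 - p3),
                }
            )
    return pd.DataFrame(rows)


def render_flow_table(flows: Sequence[FlowResult], mode: Mode = "printed") -> str:
    """Human-readable passage-through-the-pipeline table."""
    return flow_table(flows, mode).to_string(index=False)


def summary_table(
    results: Sequence[ScenarioResult],
    mode: Mode = "printed",
    baseline: Optional[ScenarioResult] = None,
) -> pd.DataFrame:
    """Per-scenario headline numbers; deltas vs the baseline (default: first)."""
    if len(results) == 0:
        raise ValueError("at least one scenario result is required")
    base = baseline if baseline is not None else results[0]
    rows = []
    for r in results:
        m = productivity_metrics(r.flow, baseline=base.flow, mode=mode)
        deltas = compare_scenarios(r, base, mode=mode)
        rows.append(
            {
                "scenario": r.scenario.name,
                "pass_phase2_pct": m.pass_phase2_pct,
                "productivity_pct": m.productivity_pct,
                "effective_share_phase3_pct": m.effective_share_phase3_pct,
                "false_negatives": m.false_negatives,
                "cost_phase2": r.economics.cost_phase2,
                "cost_phase3": r.economics.cost_phase3,
                "expected_return": r.economics.expected_return,
                "profit": r.economics.profit,
                "productivity_change_pct": m.productivity_change_pct,
                "profit_change_pct": deltas["profit"],
            }
        )
    return pd.DataFrame(rows)


def run_all(config: RunConfig, outdir: str | Path) -> Dict[str, Path]:
    """Run every analysis layer and write the result bundle to ``outdir``.

    Returns a mapping from artifact name to written path.  Identical
    configs (including seed) produce identical files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}

    scenarios = config.to_scenarios()
    cm = config.to_cost_model()
    mode: Mode = config.rounding

    flows = [run_flow(s) for s in scenarios]
    results = [evaluate_scenario(s, cm) for s in scenarios]

    written["flows"] = out / "flows.csv"
    flow_table(flows, mode).to_csv(written["flows"], index=False)

    written["summary"] = out / "summary.csv"
    summary_table(results, mode).to_csv(written["summary"], index=False)

    grid = SearchGrid(template=scenarios[0])
    surface = profit_surface(grid)
    written["surface"] = out / "surface.csv"
    surface.to_frame().to_csv(written["surface"], index=False)
    opt_alpha, opt_power, opt_profit = find_optimum(surface)

    cost_values = [100_000 + 25_000 * i for i in range(13)]  # $100k..$400k
    written["sweep_cost"] = out / "sweep_cost_per_participant.csv"
    sweep_cost_per_participant(scenarios, cost_values, cm).to_csv(
        written["sweep_cost"], index=False
    )

    p_values = [round(0.05 * i, 2) for i in range(1, 11)]  # 5%..50%
    written["sweep_p_eff"] = out / "sweep_p_eff.csv"
    sweep_p_eff(scenarios, p_values, cm).to_csv(written["sweep_p_eff"], index=False)

    psa_summary: Optional[dict] = None
    if config.psa.enabled:
        psa_result = run_psa(config.to_psa_spec())
        written["psa_draws"] = out / "psa_draws.csv"
        pd.concat([psa_result.draws, psa_result.profits], axis=1).to_csv(
            written["psa_draws"], index=False
        )
        psa_summary = {
            "summary": psa_result.summary.round(6).to_dict(orient="index"),
            "correlations": psa_result.correlations.round(6).to_dict(orient="index"),
        }
        written["psa_summary"] = out / "psa_summary.json"
        written["psa_summary"].write_text(json.dumps(psa_summary, indent=2))

    metadata = {
        "package": "trialflow",
        "version": __version__,
        "seed": config.seed,
        "rounding": config.rounding,
        "z_rounding": config.cost.z_rounding,
        "economies_factor": config.cost.economies_factor,
        "surface_economies_factor": grid.cost_model.economies_factor,
        "sidedness": [s.phase2.sidedness for s in config.scenarios],
        "psa_enabled": config.psa.enabled,
        "psa_portfolio_sampling": config.psa.portfolio_sampling,
        "cost_sweep_convention": "phase II and phase III program costs both scale "
        "proportionally to cost_per_participant",
        "optimum": {"alpha": opt_alpha, "power": opt_power, "profit": opt_profit},
    }
    written["metadata"] = out / "metadata.json"
    written["metadata"].write_text(json.dumps(metadata, indent=2))
    return written
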