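"""Matplotlib views of surfaces, sweeps and PSA distributions."""

from __future__ import annotations

from typing import Optional

import matplotlib.pyplot as plt
import pandas as pd

from .psa import PsaResult
from .search import ProfitSurface

__all__ = ["plot_profit_vs_power", "plot_sweep", "plot_psa_profits"]


def plot_profit_vs_power(surface: ProfitSurface, ax: Optional[plt.Axes] = None) -> plt.Axes:
    """Profit against phase II power, one line per alpha level."""
    if ax is None:
        _, ax = plt.subplots()
    for i, a in enumerate(surface.alpha_values):
        ax.plot(surface.power_values, surface.profit[i], label=f"alpha = {a:g}")
    ax.set_xlabel("phase II power")
    ax.set_ylabel("profit ($M)")
    ax.legend()
    return ax


def plot_sweep(
    sweep: pd.DataFrame, x: str, ax: Optional[plt.Axes] = None
) -> plt.Axes:
    """Profit curves from a sweep table (``x`` names the swept column)."""
    if ax is None:
        _, ax = plt.subplots()
    for name, group in sweep.groupby("scenario"):
        ax.plot(group[x], group["profit"], label=str(name))
    ax.set_xlabel(x)
    ax.set_ylabel("profit ($M)")
    ax.legend()
    return ax


def plot_psa_profits(result: PsaResult, ax: Optional[plt.Axes] = None, bins: int = 60) -> plt.Axes:
    """Overlaid histograms of simulated profit per scenario."""
    if ax is None:
        _, ax = plt.subplots()
    for name in result.profits.columns:
        ax.hist(result.profits[name], bins=bins, alpha=0.5, label=name, density=True)
    ax.set_xlabel("profit ($M)")
    ax.set_ylabel("density")
    ax.legend()
    return ax
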