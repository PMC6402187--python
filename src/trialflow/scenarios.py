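"""The four canonical development scenarios.

All share phase III (two confirmatory trials, alpha 5% / power 90% each,
composite 0.25% / 81%), 100 candidates and 25% effective; they differ only
in the single phase II trial's thresholds:

* Scenario 1 "Status quo"        — alpha 5%,  power 50%
* Scenario 2 "High power"        — alpha 5%,  power 80%
* Scenario 3 "Stringent alpha"   — alpha 1%,  power 50%
* Scenario 4 "Lenient alpha, high power" — alpha 20%, power 95% (the
  profit-surface optimum)
"""

from __future__ import annotations

from typing import Tuple

from .design import StageDesign
from .flow import Scenario

__all__ = [
    "REFERENCE_PHASE2",
    "DEFAULT_PHASE3",
    "scenario_1",
    "scenario_2",
    "scenario_3",
    "scenario_4",
    "default_scenarios",
]

#: Reference phase II design (Scenario 1): the $40M / 200-participant study.
REFERENCE_PHASE2 = StageDesign(0.05, 0.50, n_trials=1)

#: Two confirmatory trials at alpha 5% / power 90% each.
DEFAULT_PHASE3 = StageDesign(0.05, 0.90, n_trials=2)


def scenario_1(p_eff: float = 0.25, n_candidates: float = 100) -> Scenario:
    """Status quo: phase II alpha 5%, power 50%."""
    return Scenario("Scenario 1", REFERENCE_PHASE2, DEFAULT_PHASE3, p_eff, n_candidates)


def scenario_2(p_eff: float = 0.25, n_candidates: float = 100) -> Scenario:
    """High power at phase II: alpha 5%, power 80%."""
    return Scenario(
        "Scenario 2", StageDesign(0.05, 0.80), DEFAULT_PHASE3, p_eff, n_candidates
    )


def scenario_3(p_eff: float = 0.25, n_candidates: float = 100) -> Scenario:
    """Stringent alpha at phase II: alpha 1%, power 50%."""
    return Scenario(
        "Scenario 3", StageDesign(0.01, 0.50), DEFAULT_PHASE3, p_eff, n_candidates
    )


def scenario_4(p_eff: float = 0.25, n_candidates: float = 100) -> Scenario:
    """Lenient alpha, high power at phase II: alpha 20%, power 95%."""
    return Scenario(
        "Scenario 4", StageDesign(0.20, 0.95), DEFAULT_PHASE3, p_eff, n_candidates
    )


def default_scenarios(p_eff: float = 0.25, n_candidates: float = 100) -> Tuple[Scenario, ...]:
    """The four canonical scenarios, Scenario 1 first (the baseline)."""
    return (
        scenario_1(p_eff, n_candidates),
        scenario_2(p_eff, n_candidates),
        scenario_3(p_eff, n_candidates),
        scenario_4(p_eff, n_candidates),
    )
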