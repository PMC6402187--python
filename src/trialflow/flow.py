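"""Expected-count propagation of a candidate portfolio through phase II/III.

A portfolio of ``n_candidates`` treatments enters phase II; a fraction
``p_eff`` is truly effective.  Effective treatments pass a phase with its
composite power, ineffective ones with its composite type-I error rate.
Failures exit permanently.  Counts are expectations (continuous reals);
``mode="printed"`` reproduces the published convention of rounding each
expected count half-up to one decimal before forming derived percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

from .design import StageDesign
from .rounding import round1

__all__ = [
    "Mode",
    "Scenario",
    "FlowResult",
    "Classification",
    "FlowMetrics",
    "run_flow",
    "classify_outcomes",
    "productivity_metrics",
]

Mode = Literal["exact", "printed"]


def _default_phase3() -> StageDesign:
    # regulatory convention: two independent confirmatory trials,
    # each at alpha 5% / power 90%  =>  composite 0.25% / 81%
    return StageDesign(0.05, 0.90, n_trials=2)


@dataclass(frozen=True)
class Scenario:
    """A full development configuration: phase II + phase III + candidate mix."""

    name: str
    phase2: StageDesign
    phase3: StageDesign = field(default_factory=_default_phase3)
    p_eff: float = 0.25
    n_candidates: float = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_eff <= 1.0:
            raise ValueError(f"p_eff must be in [0, 1], got {self.p_eff!r}")
        if self.n_candidates <= 0:
            raise ValueError(f"n_candidates must be positive, got {self.n_candidates!r}")


@dataclass(frozen=True)
class FlowResult:
    """Counts of effective/ineffective treatments at each pipeline stage.

    Stores entrants and passers per class; failures and phase III entrants
    are derived, so the conservation identities (pass + fail = enter,
    phase III entrants = phase II passers) hold exactly by construction.
    Holds expected (continuous) counts from :func:`run_flow` or realized
    integer counts from a stochastic portfolio draw.
    """

    scenario: Scenario
    eff_enter: float
    eff_pass2: float
    eff_pass3: float
    ineff_enter: float
    ineff_pass2: float
    ineff_pass3: float

    def __post_init__(self) -> None:
        chain = [
            (self.eff_enter, self.eff_pass2, self.eff_pass3),
            (self.ineff_enter, self.ineff_pass2, self.ineff_pass3),
        ]
        for enter, p2, p3 in chain:
            if not (enter >= p2 >= p3 >= 0.0):
                raise ValueError("stage counts must satisfy enter >= pass2 >= pass3 >= 0")

    # -- derived counts -------------------------------------------------
    @property
    def eff_fail2(self) -> float:
        return self.eff_enter - self.eff_pass2

    @property
    def eff_fail3(self) -> float:
        return self.eff_pass2 - self.eff_pass3

    @property
    def ineff_fail2(self) -> float:
        return self.ineff_enter - self.ineff_pass2

    @property
    def ineff_fail3(self) -> float:
        return self.ineff_pass2 - self.ineff_pass3

    @property
    def total_enter(self) -> float:
        return self.eff_enter + self.ineff_enter

    @property
    def phase3_entrants(self) -> float:
        return self.eff_pass2 + self.ineff_pass2

    @property
    def total_pass3(self) -> float:
        return self.eff_pass3 + self.ineff_pass3


@dataclass(frozen=True)
class Classification:
    """Expected counts of the four development outcomes.

    True positives pass both phases and are effective; false negatives are
    effective treatments lost at either phase (the missed opportunities);
    false positives are ineffective treatments reaching approval; true
    negatives are ineffective treatments correctly screened out.
    """

    true_positives: float
    false_negatives: float
    false_positives: float
    true_negatives: float

    @property
    def total(self) -> float:
        return (
            self.true_positives
            + self.false_negatives
            + self.false_positives
            + self.true_negatives
        )


@dataclass(frozen=True)
class FlowMetrics:
    """Derived pipeline efficiency measures (percentages on 0–100 scale)."""

    productivity_pct: float
    pass_phase2_pct: float
    pass_phase3_pct: float
    effective_share_phase3_pct: float
    false_negatives: float
    productivity_change_pct: Optional[float] = None


def run_flow(scenario: Scenario) -> FlowResult:
    """Propagate expected counts of both classes through both phases."""
    n_eff = scenario.p_eff * scenario.n_candidates
    n_ineff = (1.0 - scenario.p_eff) * scenario.n_candidates
    eff_pass2 = n_eff * scenario.phase2.power_composite
    ineff_pass2 = n_ineff * scenario.phase2.alpha_composite
    return FlowResult(
        scenario=scenario,
        eff_enter=n_eff,
        eff_pass2=eff_pass2,
        eff_pass3=eff_pass2 * scenario.phase3.power_composite,
        ineff_enter=n_ineff,
        ineff_pass2=ineff_pass2,
        ineff_pass3=ineff_pass2 * scenario.phase3.alpha_composite,
    )


def classify_outcomes(flow: FlowResult, mode: Mode = "exact") -> Classification:
    """Split the portfolio into TP / FN / FP / TN expected counts.

    In printed mode each per-stage count is rounded to one decimal before
    the per-class sums are formed (so e.g. a false-negative total of
    12.5 + 2.4 = 14.9 matches the published table).
    """
    if mode == "printed":
        return Classification(
            true_positives=round1(flow.eff_pass3),
            false_negatives=round1(flow.eff_fail2) + round1(flow.eff_fail3),
            false_positives=round1(flow.ineff_pass3),
            true_negatives=round1(flow.ineff_fail2) + round1(flow.ineff_fail3),
        )
    return Classification(
        true_positives=flow.eff_pass3,
        false_negatives=flow.eff_enter - flow.eff_pass3,
        false_positives=flow.ineff_pass3,
        true_negatives=flow.ineff_enter - flow.ineff_pass3,
    )


def productivity_metrics(
    flow: FlowResult, baseline: Optional[FlowResult] = None, mode: Mode = "exact"
) -> FlowMetrics:
    """Pipeline efficiency measures, optionally relative to a baseline.

    productivity = true positives / all effective entrants.  The baseline
    must share the candidate mix (same ``n_candidates`` and ``p_eff``).
    In printed mode every count is rounded to one decimal *before* each
    ratio, and each resulting percentage is itself printed to one decimal.
    """
    if baseline is not None:
        s, b = flow.scenario, baseline.scenario
        if (s.n_candidates, s.p_eff) != (b.n_candidates, b.p_eff):
            raise ValueError(
                "baseline flow has a different candidate mix "
                f"(n={b.n_candidates}, p_eff={b.p_eff}) than the flow under "
                f"comparison (n={s.n_candidates}, p_eff={s.p_eff})"
            )

    def metrics_of(f: FlowResult) -> FlowMetrics:
        if mode == "printed":
            e2, i2 = round1(f.eff_pass2), round1(f.ineff_pass2)
            e3, i3 = round1(f.eff_pass3), round1(f.ineff_pass3)
            fn = round1(f.eff_fail2) + round1(f.eff_fail3)
            entrants3 = e2 + i2
            return FlowMetrics(
                productivity_pct=round1(100.0 * e3 / f.eff_enter),
                pass_phase2_pct=round1(100.0 * entrants3 / f.total_enter),
                pass_phase3_pct=(
                    round1(100.0 * (e3 + i3) / entrants3) if entrants3 > 0 else float("nan")
                ),
                effective_share_phase3_pct=(
                    round1(100.0 * e2 / entrants3) if entrants3 > 0 else float("nan")
                ),
                false_negatives=fn,
            )
        entrants3 = f.phase3_entrants
        return FlowMetrics(
            productivity_pct=100.0 * f.eff_pass3 / f.eff_enter,
            pass_phase2_pct=100.0 * entrants3 / f.total_enter,
            pass_phase3_pct=(
                100.0 * f.total_pass3 / entrants3 if entrants3 > 0 else float("nan")
            ),
            effective_share_phase3_pct=(
                100.0 * f.eff_pass2 / entrants3 if entrants3 > 0 else float("nan")
            ),
            false_negatives=f.eff_enter - f.eff_pass3,
        )

    m = metrics_of(flow)
    if baseline is None:
        return m
    mb = metrics_of(baseline)
    change = 100.0 * (m.productivity_pct - mb.productivity_pct) / mb.productivity_pct
    if mode == "printed":
        change = round1(change)
    return FlowMetrics(
        productivity_pct=m.productivity_pct,
        pass_phase2_pct=m.pass_phase2_pct,
        pass_phase3_pct=m.pass_phase3_pct,
        effective_share_phase3_pct=m.effective_share_phase3_pct,
        false_negatives=m.false_negatives,
        productivity_change_pct=change,
    )
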