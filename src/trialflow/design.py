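"""Normal-approximation design calculations for two-arm trials.

Power, sample size and relative sample-size arithmetic for a two-arm
superiority comparison on a continuous endpoint, plus the operating
characteristics of a development stage that requires several independent
positive trials.  The standardized effect size (mu1 - mu0) / sigma is the
only way the underlying means and standard deviation enter; they are never
modelled separately.

Two conventions are configurable throughout:

* ``sidedness`` — whether the per-trial significance test is one- or
  two-sided.  The two-sided convention (critical value ``z_{1-alpha/2}``)
  is the default because it is the one under which the sample-size-driven
  cost ratios of the economics layer reproduce published program costs.
* ``rounding`` — ``"two_decimals"`` rounds normal quantiles to two decimal
  places (the textbook convention, e.g. 1.96 and 0.84) before they are
  squared into sample-size ratios; ``"none"`` keeps full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Tuple

from scipy import stats

__all__ = [
    "Sidedness",
    "ZRounding",
    "StageDesign",
    "EffectContext",
    "standard_normal_quantile",
    "power_two_sample",
    "required_n_per_arm",
    "sample_size_ratio",
    "composite_stage",
]

Sidedness = Literal["one-sided", "two-sided"]
ZRounding = Literal["none", "two_decimals"]


def standard_normal_quantile(p: float, rounding: ZRounding = "none") -> float:
    """Inverse of the standard normal CDF, Phi^{-1}(p).

    Parameters
    ----------
    p : float
        Probability, strictly inside (0, 1).
    rounding : {"none", "two_decimals"}
        In ``two_decimals`` mode the quantile is rounded to two decimal
        places (1.959964 -> 1.96), the convention used for printed
        sample-size ratios.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie strictly in (0, 1), got {p!r}")
    z = float(stats.norm.ppf(p))
    if rounding == "two_decimals":
        z = round(z, 2)
    elif rounding != "none":
        raise ValueError(f"unknown rounding mode {rounding!r}")
    return z


def _critical_z(alpha: float, sidedness: Sidedness, rounding: ZRounding) -> float:
    """Critical value of the per-trial test: z_{1-alpha} or z_{1-alpha/2}."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie strictly in (0, 1), got {alpha!r}")
    if sidedness == "two-sided":
        tail = alpha / 2.0
    elif sidedness == "one-sided":
        tail = alpha
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return standard_normal_quantile(1.0 - tail, rounding)


@dataclass(frozen=True)
class StageDesign:
    """Error thresholds for one development phase.

    A phase consists of ``n_trials`` independent trials that must *all*
    come out positive for a treatment to progress.  ``alpha_per_trial``
    and ``power_per_trial`` are the per-trial type-I error rate and power;
    the composite phase-level operating characteristics are their
    ``n_trials``-th powers.
    """

    alpha_per_trial: float
    power_per_trial: float
    n_trials: int = 1
    sidedness: Sidedness = "two-sided"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_per_trial < 1.0:
            raise ValueError(f"alpha_per_trial must be in (0, 1), got {self.alpha_per_trial!r}")
        if not 0.0 < self.power_per_trial < 1.0:
            raise ValueError(f"power_per_trial must be in (0, 1), got {self.power_per_trial!r}")
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials!r}")
        if self.sidedness not in ("one-sided", "two-sided"):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")

    @property
    def alpha_composite(self) -> float:
        """Probability an ineffective treatment passes the whole phase."""
        return self.alpha_per_trial ** self.n_trials

    @property
    def power_composite(self) -> float:
        """Probability an effective treatment passes the whole phase."""
        return self.power_per_trial ** self.n_trials

    def critical_z(self, rounding: ZRounding = "none") -> float:
        """Per-trial critical value z_{1-alpha} (or z_{1-alpha/2})."""
        return _critical_z(self.alpha_per_trial, self.sidedness, rounding)

    def power_z(self, rounding: ZRounding = "none") -> float:
        """Quantile of the per-trial power, z_{power} = Phi^{-1}(1-beta)."""
        return standard_normal_quantile(self.power_per_trial, rounding)


@dataclass(frozen=True)
class EffectContext:
    """A standardized effect size together with a per-arm sample size."""

    effect_size: float
    n_per_arm: int

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ValueError(f"effect_size must be positive, got {self.effect_size!r}")
        if self.n_per_arm < 2:
            raise ValueError(f"n_per_arm must be >= 2, got {self.n_per_arm!r}")


def power_two_sample(
    ctx: EffectContext, alpha: float, sidedness: Sidedness = "two-sided"
) -> float:
    """Power of a two-arm z-test: 1 - Phi(z_crit - ES * sqrt(n/2)).

    ``n`` is the per-arm sample size (total study size is ``2 n``); the
    sqrt(n/2) factor is the usual two-arm standard-error scaling.  The
    vanishing lower-tail rejection region of the two-sided test is
    ignored, which is the standard design approximation.
    """
    z_crit = _critical_z(alpha, sidedness, "none")
    lam = ctx.effect_size * math.sqrt(ctx.n_per_arm / 2.0)
    return float(1.0 - stats.norm.cdf(z_crit - lam))


def required_n_per_arm(
    effect_size: float,
    alpha: float,
    power: float,
    sidedness: Sidedness = "two-sided",
    rounding: ZRounding = "none",
) -> int:
    """Smallest per-arm n achieving the requested power.

    Closed form ``ceil(2 (z_alpha + z_power)^2 / ES^2)``, with a one-step
    minimality correction guarding against floating-point slop at exact
    integer solutions.
    """
    if effect_size <= 0:
        raise ValueError(f"effect_size must be positive, got {effect_size!r}")
    if not 0.0 < power < 1.0:
        raise ValueError(f"power must lie strictly in (0, 1), got {power!r}")
    z_a = _critical_z(alpha, sidedness, rounding)
    z_p = standard_normal_quantile(power, rounding)
    if z_a + z_p <= 0.0:
        raise ValueError(
            f"requested power {power} is below the floor implied by alpha={alpha}; "
            "no sample size achieves it"
        )
    n_exact = 2.0 * (z_a + z_p) ** 2 / effect_size**2
    n = max(2, math.ceil(n_exact))
    if n > 2 and power_two_sample(EffectContext(effect_size, n - 1), alpha, sidedness) >= power:
        n -= 1
    return n


def sample_size_ratio(
    design: StageDesign, reference: StageDesign, rounding: ZRounding = "none"
) -> float:
    """Per-arm sample-size ratio of two designs at a common effect size.

    ``((z_a + z_p) / (z_a_ref + z_p_ref))^2`` — the effect size cancels, so
    the ratio depends only on the error thresholds.  This is what scales
    program costs across designs.
    """
    num = design.critical_z(rounding) + design.power_z(rounding)
    den = reference.critical_z(rounding) + reference.power_z(rounding)
    if den <= 0.0:
        raise ValueError("reference design has non-positive z_alpha + z_power")
    return (num / den) ** 2


def composite_stage(stage: StageDesign) -> Tuple[float, float]:
    """(composite alpha, composite power) of a k-trial phase."""
    return stage.alpha_composite, stage.power_composite
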