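"""Incremental cost-effectiveness outcomes: ICER, INHB, INMB, dominance.

For a treatment (index 1) vs comparator (index 0) with mean discounted costs
C and effects E (QALYs), and willingness-to-pay threshold lambda:

    ICER = (C1 - C0) / (E1 - E0)
    INHB = (E1 - E0) - (C1 - C0) / lambda      [QALYs]
    INMB = (E1 - E0) * lambda - (C1 - C0)      [currency]

A strategy is *dominant* when it costs less and gains effect, *dominated*
when it costs more and loses effect; the ICER ratio is not meaningful in
either case (nor when the effect difference is zero) and is tagged instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["StrategyResult", "IncrementalResult", "incremental"]


@dataclass(frozen=True)
class StrategyResult:
    """One strategy's mean discounted cost and effect."""

    label: str
    cost: float
    effect: float

    def __post_init__(self) -> None:
        if self.effect < 0:
            raise ValueError("effect (QALYs) must be >= 0")


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental economics of treatment vs comparator at one threshold."""

    treat_label: str
    comp_label: str
    delta_cost: float
    delta_effect: float
    icer: float  # nan when tagged
    dominance: str | None  # "dominant" | "dominated" | "undefined" | None
    inhb: float
    inmb: float
    wtp: float

    @property
    def cost_effective(self) -> bool:
        """Positive net benefit at the stated threshold."""
        return self.inmb > 0


def incremental(
    treat: StrategyResult, comp: StrategyResult, wtp: float
) -> IncrementalResult:
    """Incremental cost, effect, ICER (or dominance tag), INHB and INMB."""
    if wtp <= 0:
        raise ValueError("willingness-to-pay must be positive")
    d_cost = treat.cost - comp.cost
    d_eff = treat.effect - comp.effect
    dominance: str | None = None
    if d_eff == 0:
        icer = math.nan
        dominance = "undefined"
    else:
        icer = d_cost / d_eff
        if d_cost < 0 and d_eff > 0:
            dominance = "dominant"
        elif d_cost > 0 and d_eff < 0:
            dominance = "dominated"
    inhb = d_eff - d_cost / wtp
    inmb = d_eff * wtp - d_cost
    return IncrementalResult(
        treat_label=treat.label,
        comp_label=comp.label,
        delta_cost=d_cost,
        delta_effect=d_eff,
        icer=icer,
        dominance=dominance,
        inhb=inhb,
        inmb=inmb,
        wtp=wtp,
    )
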