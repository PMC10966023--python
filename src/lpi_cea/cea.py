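"""Pairwise incremental cost-effectiveness comparison of two arms."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import ArmResult

__all__ = ["CEAResult", "compare", "to_gbp"]

COMPARATOR_DOMINATED = "comparator_dominated"
INTERVENTION_DOMINATED = "intervention_dominated"
TRADEOFF = "tradeoff"
INDIFFERENT = "indifferent"


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison (intervention minus comparator).

    ``icer`` is None when the QALY difference is zero; a negative ICER
    with ``dominance == 'comparator_dominated'`` is reported as
    "dominant" rather than as a number.
    """

    scenario_label: str
    delta_cost: float
    delta_qaly: float
    icer: float | None
    nmb: float
    wtp: float
    dominance: str
    jpy_per_gbp: float = 160.0

    @property
    def icer_gbp(self) -> float | None:
        return None if self.icer is None else to_gbp(self.icer, self.jpy_per_gbp)

    @property
    def icer_label(self) -> str:
        if self.dominance == COMPARATOR_DOMINATED:
            return "dominant"
        if self.dominance == INTERVENTION_DOMINATED:
            return "dominated"
        if self.icer is None:
            return "undefined"
        return f"{self.icer:,.0f}"

    def to_row(self) -> dict:
        return {
            "scenario": self.scenario_label,
            "delta_cost_jpy": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer_jpy_per_qaly": None if self.icer is None else round(self.icer),
            "icer_gbp_per_qaly": self.icer_gbp,
            "nmb_jpy": self.nmb,
            "dominance": self.dominance,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_row()])


def compare(intervention: ArmResult, comparator: ArmResult,
            wtp: float, jpy_per_gbp: float = 160.0) -> CEAResult:
    """Incremental cost, QALYs, ICER and net monetary benefit.

    Both results must come from the same scenario.  Dominance: the
    comparator is dominated when the intervention costs less and yields
    more QALYs; the intervention is dominated in the mirror case;
    exactly equal costs and QALYs are indifferent; anything else is a
    trade-off priced by the ICER.
    """
    if intervention.scenario != comparator.scenario:
        raise ValueError("arms were run under different scenarios")
    d_cost = intervention.total_cost - comparator.total_cost
    d_qaly = intervention.total_qaly - comparator.total_qaly
    icer = d_cost / d_qaly if d_qaly != 0.0 else None
    nmb = wtp * d_qaly - d_cost
    if d_cost < 0 and d_qaly > 0:
        dom = COMPARATOR_DOMINATED
    elif d_cost > 0 and d_qaly < 0:
        dom = INTERVENTION_DOMINATED
    elif d_cost == 0 and d_qaly == 0:
        dom = INDIFFERENT
    else:
        dom = TRADEOFF
    return CEAResult(
        scenario_label=intervention.scenario.label,
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        icer=icer,
        nmb=nmb,
        wtp=wtp,
        dominance=dom,
        jpy_per_gbp=jpy_per_gbp,
    )


def to_gbp(jpy: float, rate: float) -> int:
    """Convert JPY to pounds sterling, rounded to the nearest pound."""
    if rate <= 0:
        raise ValueError("exchange rate must be positive")
    return int(round(jpy / rate))
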