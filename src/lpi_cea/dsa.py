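"""Deterministic sensitivity analyses: scenario sweep over cohort
entry/exit ages and one-way parameter excursions with tornado ranking."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cea import CEAResult, compare
from .cohort import LPI, OBSERVATION, ArmResult, run_cohort
from .parameters import ParameterSet, ScenarioConfig

__all__ = [
    "BASE_SCENARIO",
    "default_scenarios",
    "run_comparison",
    "scenario_sweep",
    "TornadoEntry",
    "one_way",
    "tornado",
]

BASE_SCENARIO = ScenarioConfig(40, 59, label="40-59 (20-year horizon, base-case)")


def default_scenarios() -> tuple[ScenarioConfig, ...]:
    """The base case plus the six entry/exit-age variants."""
    return (
        BASE_SCENARIO,
        ScenarioConfig(40, 54),
        ScenarioConfig(40, 49),
        ScenarioConfig(50, 69),
        ScenarioConfig(50, 64),
        ScenarioConfig(50, 59),
        ScenarioConfig(40, 99),
    )


def run_comparison(params: ParameterSet, scenario: ScenarioConfig
                   ) -> tuple[ArmResult, ArmResult, CEAResult]:
    """Run both arms under one scenario and compare them."""
    lpi = run_cohort(params, LPI, scenario)
    obs = run_cohort(params, OBSERVATION, scenario)
    return lpi, obs, compare(lpi, obs, params.wtp, params.jpy_per_gbp)


def scenario_sweep(params: ParameterSet,
                   scenarios: tuple[ScenarioConfig, ...] | None = None
                   ) -> pd.DataFrame:
    """Cost, QALYs and ICER of both arms for each scenario."""
    rows = []
    for sc in scenarios or default_scenarios():
        lpi, obs, cea = run_comparison(params, sc)
        rows.append({
            "scenario": sc.label,
            "entry_age": sc.entry_age,
            "exit_age": sc.exit_age,
            "horizon": sc.horizon,
            "cost_lpi_jpy": lpi.total_cost,
            "cost_observation_jpy": obs.total_cost,
            "qaly_lpi": lpi.total_qaly,
            "qaly_observation": obs.total_qaly,
            "delta_cost_jpy": cea.delta_cost,
            "delta_qaly": cea.delta_qaly,
            "icer_jpy_per_qaly": cea.icer,
            "icer_label": cea.icer_label,
            "dominance": cea.dominance,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TornadoEntry:
    """ICER excursion of one parameter over its DSA range."""

    parameter: str
    low: float
    high: float
    icer_at_low: float | None
    icer_at_high: float | None
    nmb_at_low: float
    nmb_at_high: float
    dominance_change: bool

    @property
    def span(self) -> float:
        """|ICER(high) - ICER(low)|; falls back to the net-monetary-benefit
        span when an excursion makes the ICER undefined or dominant."""
        if self.icer_at_low is not None and self.icer_at_high is not None \
                and not self.dominance_change:
            return abs(self.icer_at_high - self.icer_at_low)
        return abs(self.nmb_at_high - self.nmb_at_low)

    @property
    def direction(self) -> int:
        """+1 when raising the parameter raises the ICER, -1 when it lowers
        it, 0 for a flat excursion."""
        if self.icer_at_low is None or self.icer_at_high is None:
            d = self.nmb_at_low - self.nmb_at_high  # higher NMB = lower ICER
        else:
            d = self.icer_at_high - self.icer_at_low
        return 0 if d == 0 else (1 if d > 0 else -1)

    def to_row(self) -> dict:
        return {
            "parameter": self.parameter,
            "low": self.low,
            "high": self.high,
            "icer_low": self.icer_at_low,
            "icer_high": self.icer_at_high,
            "span": self.span,
            "direction": self.direction,
        }


def one_way(params: ParameterSet, parameter_id: str,
            scenario: ScenarioConfig = BASE_SCENARIO) -> TornadoEntry:
    """Re-run the comparison with one parameter at its DSA bounds.

    The parameter set itself is never mutated: each excursion builds a
    fresh set, so repeated calls always start from the same defaults.
    """
    p = params.get(parameter_id)  # KeyError for unknown ids
    results = []
    for bound in (p.dsa_low, p.dsa_high):
        _, _, cea = run_comparison(params.with_parameter_at(parameter_id, bound),
                                   scenario)
        results.append(cea)
    lo, hi = results
    dom_change = (lo.dominance != hi.dominance)
    return TornadoEntry(
        parameter=parameter_id,
        low=p.dsa_low,
        high=p.dsa_high,
        icer_at_low=lo.icer if lo.dominance == "tradeoff" else None,
        icer_at_high=hi.icer if hi.dominance == "tradeoff" else None,
        nmb_at_low=lo.nmb,
        nmb_at_high=hi.nmb,
        dominance_change=dom_change,
    )


def tornado(params: ParameterSet, scenario: ScenarioConfig = BASE_SCENARIO,
            top_k: int = 12) -> list[TornadoEntry]:
    """One-way excursions for every ranged parameter, sorted by span
    (descending, ties kept in parameter order), truncated to ``top_k``."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    entries = [one_way(params, p.name, scenario)
               for p in params if p.varied_in_dsa]
    entries.sort(key=lambda e: -e.span)  # stable: ties stay in input order
    return entries[:top_k]


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    df = pd.DataFrame([e.to_row() for e in entries])
    df["rank"] = range(1, len(df) + 1)
    return df
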