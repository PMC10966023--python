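"""Individual-level microsimulation of the angle-closure model.

This is the brute-force validator for the cohort engine (and the
package's synthetic trajectory generator): patients walk the identical
state-transition graph with per-cycle multinomial draws, accruing the
same rewards under the same annuity-due discounting.  Rewards are taken
from :func:`lpi_cea.cohort.cycle_rewards`, so any disagreement with the
cohort engine isolates to the transition logic.

Unlike the cohort engine, trabeculectomy is simulated as an explicit
event: a patient in PACG draws the surgery with the age-bracket
probability, paying the surgery cost and spending that year at the
surgery utility.  ``trab_mode='once_only'`` restricts the event to once
per patient, quantifying how little the cohort engine's memoryless
expected-value treatment matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    CohortTrace,
    build_state_space,
    discount_factors,
    reward_vectors,
    transition_matrix,
)
from .parameters import ParameterSet, ScenarioConfig, age_bracket_value

__all__ = [
    "MicrosimResult",
    "simulate_patients",
    "trajectories_to_trace",
]


@dataclass(frozen=True)
class MicrosimResult:
    """Simulated patient trajectories and their accrued rewards."""

    arm: str
    scenario: ScenarioConfig
    seed: int
    trab_mode: str
    state_names: tuple[str, ...]
    states: np.ndarray      # (n_patients, horizon) int8 state indices
    trab_events: np.ndarray  # (n_patients, horizon) bool
    cost: np.ndarray        # (n_patients,) discounted JPY
    qaly: np.ndarray        # (n_patients,) discounted QALYs
    cycle_cost: np.ndarray  # (horizon,) mean discounted JPY per cycle
    cycle_qaly: np.ndarray  # (horizon,) mean discounted QALYs per cycle

    @property
    def n_patients(self) -> int:
        return self.states.shape[0]

    @property
    def horizon(self) -> int:
        return self.states.shape[1]

    @property
    def mean_cost(self) -> float:
        return float(self.cost.mean())

    @property
    def mean_qaly(self) -> float:
        return float(self.qaly.mean())

    @property
    def se_cost(self) -> float:
        return float(self.cost.std(ddof=1) / np.sqrt(self.n_patients))

    @property
    def se_qaly(self) -> float:
        return float(self.qaly.std(ddof=1) / np.sqrt(self.n_patients))

    def ever_in(self, state: str) -> np.ndarray:
        """Per-patient flag: visited ``state`` at any recorded cycle."""
        return (self.states == self.state_names.index(state)).any(axis=1)

    def to_frame(self, max_patients: int | None = None) -> pd.DataFrame:
        """Long trajectory table (patient, cycle, age, state, events)."""
        n = self.n_patients if max_patients is None else min(
            max_patients, self.n_patients)
        pat, cyc = np.meshgrid(np.arange(n), np.arange(self.horizon),
                               indexing="ij")
        names = np.array(self.state_names)
        return pd.DataFrame({
            "patient": pat.ravel(),
            "cycle": cyc.ravel(),
            "age": self.scenario.entry_age + cyc.ravel(),
            "state": names[self.states[:n].ravel()],
            "trabeculectomy": self.trab_events[:n].ravel(),
        })


def simulate_patients(params: ParameterSet, arm: str, scenario: ScenarioConfig,
                      n_patients: int, seed: int = 0,
                      trab_mode: str = "memoryless") -> MicrosimResult:
    """Simulate ``n_patients`` independent trajectories.

    Draw order per cycle: one transition uniform and one trabeculectomy
    uniform per patient, so trajectories are identical across
    ``trab_mode`` settings at the same seed (common random numbers).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if trab_mode not in ("memoryless", "once_only"):
        raise ValueError(f"unknown trab_mode {trab_mode!r}")

    space = build_state_space(arm)
    societal = params.societal if scenario.perspective == "societal" else None
    if scenario.perspective == "societal" and societal is None:
        raise ValueError("societal perspective requires societal inputs")
    horizon = scenario.horizon
    rng = np.random.default_rng(seed)

    cum = transition_matrix(params, arm, scenario.entry_age).cumsum(axis=1)
    disc = discount_factors(params.discount_rate, horizon)
    i_pacg = space.index("PACG")

    state = np.zeros(n_patients, dtype=np.int8)  # everyone starts in PACS_y1
    had_trab = np.zeros(n_patients, dtype=bool)
    states = np.empty((n_patients, horizon), dtype=np.int8)
    trab_events = np.zeros((n_patients, horizon), dtype=bool)
    cost = np.zeros(n_patients)
    qaly = np.zeros(n_patients)
    cycle_cost = np.zeros(horizon)
    cycle_qaly = np.zeros(horizon)
    vec_cache: dict[bool, tuple[np.ndarray, np.ndarray]] = {}

    for t in range(horizon):
        age = scenario.age_at(t)
        key = age < 50
        if key not in vec_cache:
            vec_cache[key] = reward_vectors(params, arm, age, societal,
                                            trab="none")
        cvec, uvec = vec_cache[key]
        states[:, t] = state

        # explicit trabeculectomy event while in PACG
        p_tr = age_bracket_value(params, "trab_prob", age)
        u_trab_draw = rng.random(n_patients)
        event = (state == i_pacg) & (u_trab_draw < p_tr)
        if trab_mode == "once_only":
            event &= ~had_trab
        had_trab |= event
        trab_events[:, t] = event
        cost_t = disc[t] * (cvec[state]
                            + np.where(event, params.c_trab, 0.0))
        qaly_t = disc[t] * (uvec[state]
                            + np.where(event, params.u_trab - params.u_pacg,
                                       0.0))
        cost += cost_t
        qaly += qaly_t
        cycle_cost[t] = cost_t.mean()
        cycle_qaly[t] = qaly_t.mean()

        u_move = rng.random(n_patients)
        state = (u_move[:, None] > cum[state]).sum(axis=1).astype(np.int8)

    return MicrosimResult(
        arm=arm, scenario=scenario, seed=seed, trab_mode=trab_mode,
        state_names=space.states, states=states, trab_events=trab_events,
        cost=cost, qaly=qaly, cycle_cost=cycle_cost, cycle_qaly=cycle_qaly,
    )


def trajectories_to_trace(result: MicrosimResult,
                          *more: MicrosimResult) -> CohortTrace:
    """Empirical per-cycle occupancy fractions from simulated trajectories.

    All inputs must come from the same arm and scenario; the occupancy
    rows sum to 1 by construction.
    """
    batches = (result,) + more
    if any(r.arm != result.arm or r.scenario != result.scenario
           for r in batches):
        raise ValueError("trajectories mix arms or scenarios")
    states = np.concatenate([r.states for r in batches], axis=0)
    if states.size == 0:
        raise ValueError("no trajectories supplied")
    n, horizon = states.shape
    k = len(result.state_names)
    occupancy = np.stack(
        [np.bincount(states[:, t].astype(np.int64), minlength=k) / n
         for t in range(horizon)])
    weights = np.array([r.n_patients for r in batches], dtype=float)
    weights /= weights.sum()
    per_cycle_cost = sum(w * r.cycle_cost for w, r in zip(weights, batches))
    per_cycle_qaly = sum(w * r.cycle_qaly for w, r in zip(weights, batches))
    return CohortTrace(result.arm, result.scenario.entry_age,
                       result.state_names, occupancy,
                       per_cycle_cost, per_cycle_qaly)
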