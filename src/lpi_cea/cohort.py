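"""Markov cohort engine for the angle-closure model.

Two strategy arms share an irreversible progression chain
PACS -> PAC -> PACG -> unilateral blindness -> bilateral blindness,
with first-year tunnel states carrying first-year costs (the
prophylactic iridotomy or the first observation year in PACS, lens
extraction on entry to PAC).  The observation arm additionally exposes
PACS patients to an acute angle-closure crisis (AACC): a one-cycle
state followed by an open-angle PACS state that progresses at the
iridotomy-arm rate.  There is no dead state.

Conventions: yearly cycles; rewards accrue at cycle start and the first
cycle is undiscounted (annuity-due); no half-cycle correction;
trabeculectomy is a memoryless expected-value event within PACG each
cycle (its probability scales the surgery cost and blends the utility).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    ParameterSet,
    ScenarioConfig,
    SocietalInputs,
    age_bracket_value,
)

__all__ = [
    "LPI",
    "OBSERVATION",
    "ARMS",
    "StateSpace",
    "CohortTrace",
    "ArmResult",
    "build_state_space",
    "transition_matrix",
    "cycle_rewards",
    "run_cohort",
    "discount_factors",
]

LPI = "lpi"
OBSERVATION = "observation"
ARMS = (LPI, OBSERVATION)

_LPI_STATES = ("PACS_y1", "PACS", "PAC_y1", "PAC", "PACG",
               "UNIBLIND", "BIBLIND")
_OBS_STATES = _LPI_STATES + ("AACC", "PACS_LPIOPEN")


@dataclass(frozen=True)
class StateSpace:
    """Ordered health states for one strategy arm."""

    arm: str
    states: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self.states.index(state)

    def __contains__(self, state: str) -> bool:
        return state in self.states


def build_state_space(arm: str) -> StateSpace:
    if arm == LPI:
        return StateSpace(arm, _LPI_STATES)
    if arm == OBSERVATION:
        return StateSpace(arm, _OBS_STATES)
    raise ValueError(f"unknown arm {arm!r}; expected 'lpi' or 'observation'")


def transition_matrix(params: ParameterSet, arm: str,
                      age: float = 40.0) -> np.ndarray:
    """Row-stochastic yearly transition matrix for one arm.

    The tunnel states exit to their established twin with the same
    clinical transition probabilities as the twin itself; bilateral
    blindness is absorbing.  ``age`` is part of the contract for
    age-dependent inputs; none of the default transition probabilities
    is age-bracketed (the trabeculectomy probability enters the rewards,
    not the transitions).
    """
    if age < 40:
        raise ValueError(f"age {age} below model entry age 40")
    space = build_state_space(arm)
    ix = space.index
    n = space.n
    p_pac = params.p_pacs_pac_lpi if arm == LPI else params.p_pacs_pac_obs
    p_pacg = params.p_pac_pacg_lpi if arm == LPI else params.p_pac_pacg_obs
    p_aacc = 0.0 if arm == LPI else params.p_pacs_aacc_obs

    T = np.zeros((n, n))
    for s in ("PACS_y1", "PACS"):
        T[ix(s), ix("PAC_y1")] = p_pac
        if arm == OBSERVATION:
            T[ix(s), ix("AACC")] = p_aacc
        T[ix(s), ix("PACS")] = 1.0 - p_pac - p_aacc
    for s in ("PAC_y1", "PAC"):
        T[ix(s), ix("PACG")] = p_pacg
        T[ix(s), ix("PAC")] = 1.0 - p_pacg
    T[ix("PACG"), ix("UNIBLIND")] = params.p_pacg_uniblind
    T[ix("PACG"), ix("PACG")] = 1.0 - params.p_pacg_uniblind
    T[ix("UNIBLIND"), ix("BIBLIND")] = params.p_uni_biblind
    T[ix("UNIBLIND"), ix("UNIBLIND")] = 1.0 - params.p_uni_biblind
    T[ix("BIBLIND"), ix("BIBLIND")] = 1.0
    if arm == OBSERVATION:
        p_open = params.p_aacc_pacs_lpiopen
        T[ix("AACC"), ix("PACS_LPIOPEN")] = p_open
        T[ix("AACC"), ix("AACC")] = 1.0 - p_open
        # after the emergency iridotomy the angle is open: iridotomy-arm
        # progression, no further crisis risk
        T[ix("PACS_LPIOPEN"), ix("PAC_y1")] = params.p_pacs_pac_lpi
        T[ix("PACS_LPIOPEN"), ix("PACS_LPIOPEN")] = 1.0 - params.p_pacs_pac_lpi

    if np.any(T < -1e-15) or np.any(np.abs(T.sum(axis=1) - 1.0) > 1e-12):
        bad = space.states[int(np.argmax(np.abs(T.sum(axis=1) - 1.0)))]
        raise ValueError(
            f"transition probabilities from {bad} do not form a distribution")
    return T


def cycle_rewards(params: ParameterSet, arm: str, state: str,
                  cycle_index: int, age: float,
                  societal: SocietalInputs | None = None,
                  trab: str = "expected") -> tuple[float, float]:
    """(cost in JPY, utility weight) accrued for one cycle in ``state``.

    PACG carries the expected-value trabeculectomy adjustment: cost plus
    p_trab * surgery cost, utility blended between the PACG and the
    surgery-year weight.  ``trab='none'`` returns the unadjusted PACG
    reward (used by the patient-level simulator, which draws the surgery
    explicitly).  A societal block adds travel and indirect costs.
    """
    space = build_state_space(arm)
    if state not in space:
        raise ValueError(f"unknown state {state!r} for arm {arm!r}")
    if trab not in ("expected", "none"):
        raise ValueError(f"unknown trab mode {trab!r}")

    if state == "PACS_y1":
        cost = params.c_pacs_lpi_y1 if arm == LPI else params.c_pacs_obs_y1
        util = params.u_pacs
    elif state == "PACS":
        cost = params.c_pacs_lpi_follow if arm == LPI else params.c_pacs_obs_follow
        util = params.u_pacs
    elif state == "PACS_LPIOPEN":
        cost = params.c_pacs_lpi_follow
        util = params.u_pacs
    elif state == "PAC_y1":
        cost = params.c_pac_y1  # lens extraction year
        util = params.u_pac
    elif state == "PAC":
        cost = params.c_pac_follow
        util = params.u_pac
    elif state == "PACG":
        cost = age_bracket_value(params, "pacg_cost", age)
        util = params.u_pacg
        if trab == "expected":
            p_tr = age_bracket_value(params, "trab_prob", age)
            cost += p_tr * params.c_trab
            util = (1.0 - p_tr) * params.u_pacg + p_tr * params.u_trab
    elif state == "UNIBLIND":
        cost = age_bracket_value(params, "uniblind_cost", age)
        util = params.u_uniblind
    elif state == "BIBLIND":
        cost = age_bracket_value(params, "biblind_cost", age)
        util = params.u_biblind
    elif state == "AACC":
        cost = params.c_aacc
        util = params.u_aacc
    else:  # pragma: no cover
        raise AssertionError(state)

    if societal is not None:
        cost += societal.travel_cost(state) + societal.indirect_cost(state)
    return float(cost), float(util)


def reward_vectors(params: ParameterSet, arm: str, age: float,
                   societal: SocietalInputs | None = None,
                   trab: str = "expected") -> tuple[np.ndarray, np.ndarray]:
    """Per-state (cost, utility) vectors at a given attained age."""
    space = build_state_space(arm)
    pairs = [cycle_rewards(params, arm, s, 0, age, societal, trab)
             for s in space.states]
    cost, util = zip(*pairs)
    return np.array(cost), np.array(util)


def discount_factors(rate: float, horizon: int) -> np.ndarray:
    """Annuity-due factors (1+r)^-t for t = 0..horizon-1."""
    return (1.0 + rate) ** -np.arange(horizon)


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle cohort occupancy and reward accrual for one arm."""

    arm: str
    entry_age: int
    states: tuple[str, ...]
    occupancy: np.ndarray  # (horizon, n_states), rows sum to 1
    cycle_cost: np.ndarray  # discounted JPY accrued per cycle
    cycle_qaly: np.ndarray  # discounted QALYs accrued per cycle

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0]

    def occupancy_of(self, state: str) -> np.ndarray:
        return self.occupancy[:, self.states.index(state)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(self.states))
        df.insert(0, "cycle", np.arange(self.horizon))
        df.insert(1, "age", self.entry_age + np.arange(self.horizon))
        df["discounted_cost"] = self.cycle_cost
        df["discounted_qaly"] = self.cycle_qaly
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ArmResult:
    """Discounted and undiscounted totals for one arm under one scenario."""

    arm: str
    scenario: ScenarioConfig
    total_cost: float
    total_qaly: float
    undiscounted_cost: float
    undiscounted_qaly: float
    trace: CohortTrace


def run_cohort(params: ParameterSet, arm: str,
               scenario: ScenarioConfig) -> ArmResult:
    """Advance the cohort through the scenario horizon and accrue rewards.

    Cycle t contributes sum_s occupancy[t, s] * reward(s, age_t) *
    (1 + r)^-t; the whole cohort starts in the first-year PACS tunnel.
    """
    horizon = scenario.horizon
    societal = None
    if scenario.perspective == "societal":
        societal = params.societal
        if societal is None:
            raise ValueError(
                "societal perspective requested but no societal inputs "
                "(indirect costs, visit schedule) were supplied")

    space = build_state_space(arm)
    T = transition_matrix(params, arm, scenario.entry_age)
    # rewards change only at the age-bracket boundary; cache per bracket
    vec_cache: dict[bool, tuple[np.ndarray, np.ndarray]] = {}

    occ = np.zeros(space.n)
    occ[space.index("PACS_y1")] = 1.0
    occupancy = np.empty((horizon, space.n))
    cost_d = np.empty(horizon)
    qaly_d = np.empty(horizon)
    cost_u = np.empty(horizon)
    qaly_u = np.empty(horizon)
    disc = discount_factors(params.discount_rate, horizon)

    for t in range(horizon):
        age = scenario.age_at(t)
        key = age < 50
        if key not in vec_cache:
            vec_cache[key] = reward_vectors(params, arm, age, societal)
        cvec, uvec = vec_cache[key]
        occupancy[t] = occ
        cost_u[t] = occ @ cvec
        qaly_u[t] = occ @ uvec
        cost_d[t] = disc[t] * cost_u[t]
        qaly_d[t] = disc[t] * qaly_u[t]
        occ = occ @ T

    trace = CohortTrace(arm, scenario.entry_age, space.states,
                        occupancy, cost_d, qaly_d)
    return ArmResult(
        arm=arm,
        scenario=scenario,
        total_cost=float(cost_d.sum()),
        total_qaly=float(qaly_d.sum()),
        undiscounted_cost=float(cost_u.sum()),
        undiscounted_qaly=float(qaly_u.sum()),
        trace=trace,
    )
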