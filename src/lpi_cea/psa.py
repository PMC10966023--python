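"""Probabilistic sensitivity analysis.

Each Monte Carlo iteration redraws every non-fixed input from a
method-of-moments distribution (beta for probabilities and utilities,
gamma for costs, SD = 10% of the mean, 5% for utilities), re-runs both
arms, and records the incremental cost and QALYs.  A parameter used by
both arms gets one draw per iteration, so the increments reflect
parameter uncertainty, not between-arm sampling noise.

Reproducibility contract: all draws come from one ``numpy`` PCG64
generator seeded with ``seed``; draws are taken parameter by parameter
in registry order, ``n_iterations`` values per parameter.  Iterations
whose sampled exit probabilities from any state exceed 1 are redrawn
(and counted) using the same generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import compare
from .cohort import LPI, OBSERVATION, run_cohort
from .parameters import ParameterSet, ScenarioConfig

__all__ = [
    "fit_beta",
    "fit_gamma",
    "sample_draws",
    "PSAResult",
    "run_psa",
    "ceac",
    "ceac_crossing",
]


def fit_beta(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments beta parameters (alpha, beta) for a given mean
    and standard deviation."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean {mean} outside (0, 1)")
    if sd <= 0.0:
        raise ValueError("beta sd must be positive")
    if sd * sd >= mean * (1.0 - mean):
        raise ValueError(
            f"infeasible moments: sd^2 = {sd*sd:g} >= mean(1-mean) = "
            f"{mean*(1-mean):g}")
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return mean * nu, (1.0 - mean) * nu


def fit_gamma(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments gamma parameters (shape, scale).  With
    sd = 0.1 * mean the shape is always 100."""
    if mean <= 0.0 or sd <= 0.0:
        raise ValueError("gamma mean and sd must be positive")
    shape = (mean / sd) ** 2
    return shape, sd * sd / mean


def _draw_parameter(rng: np.random.Generator, family: str, mean: float,
                    sd: float, n: int) -> np.ndarray:
    if family == "beta":
        a, b = fit_beta(mean, sd)
        return rng.beta(a, b, size=n)
    if family == "gamma":
        shape, scale = fit_gamma(mean, sd)
        return rng.gamma(shape, scale, size=n)
    raise ValueError(f"unknown PSA family {family!r}")


def _exit_sum_violations(draws: dict[str, np.ndarray],
                         params: ParameterSet, n: int) -> np.ndarray:
    """Boolean mask of iterations where any state's sampled exit
    probabilities sum above 1."""
    def col(name: str) -> np.ndarray:
        return draws.get(name, np.full(n, getattr(params, name)))

    bad = col("p_pacs_pac_obs") + col("p_pacs_aacc_obs") > 1.0
    for name in ("p_pacs_pac_lpi", "p_pac_pacg_lpi", "p_pac_pacg_obs",
                 "p_pacg_uniblind", "p_uni_biblind"):
        bad |= col(name) > 1.0
    return bad


def sample_draws(params: ParameterSet, n_iterations: int,
                 rng: np.random.Generator) -> tuple[dict[str, np.ndarray], int]:
    """Draw every varied parameter for every iteration.

    Returns (name -> vector of n_iterations draws, number of iterations
    that had to be resampled because a sampled probability row exceeded 1).
    """
    varied = [p for p in params if p.varied_in_psa]
    draws = {p.name: _draw_parameter(rng, p.psa_family, p.value, p.psa_sd,
                                     n_iterations)
             for p in varied}
    resampled = 0
    prob_names = [p.name for p in varied if p.kind == "probability"]
    while True:
        bad = _exit_sum_violations(draws, params, n_iterations)
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        resampled += n_bad
        for p in varied:
            if p.name in prob_names:
                draws[p.name][bad] = _draw_parameter(
                    rng, p.psa_family, p.value, p.psa_sd, n_bad)
    return draws, resampled


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration incremental (cost, QALY) samples."""

    scenario_label: str
    seed: int
    n_iterations: int
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    wtp: float
    resampled_iterations: int
    draws: pd.DataFrame | None = field(default=None, repr=False)

    def nmb(self, wtp: float | None = None) -> np.ndarray:
        wtp = self.wtp if wtp is None else wtp
        return wtp * self.delta_qaly - self.delta_cost

    def prob_cost_effective(self, wtp: float | None = None) -> float:
        """Fraction of iterations with positive net monetary benefit."""
        return float(np.mean(self.nmb(wtp) > 0.0))

    def fraction_dominant(self) -> float:
        """Fraction of iterations in the dominant quadrant (cheaper and
        more effective)."""
        return float(np.mean((self.delta_cost < 0) & (self.delta_qaly > 0)))

    def quadrants(self) -> np.ndarray:
        q = np.where(self.delta_qaly > 0,
                     np.where(self.delta_cost >= 0, "NE", "SE"),
                     np.where(self.delta_cost >= 0, "NW", "SW"))
        return q

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(self.n_iterations),
            "delta_cost_jpy": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "nmb_jpy": self.nmb(),
            "quadrant": self.quadrants(),
        })


def run_psa(params: ParameterSet, scenario: ScenarioConfig,
            n_iterations: int = 10_000, seed: int = 0,
            keep_draws: bool = False) -> PSAResult:
    """Monte Carlo propagation of parameter uncertainty.

    Fixed-family parameters (the utilities printed without a
    distribution, the certain post-crisis transition, the discount rate
    and the analysis constants) never vary.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    draws, resampled = sample_draws(params, n_iterations, rng)

    d_cost = np.empty(n_iterations)
    d_qaly = np.empty(n_iterations)
    names = list(draws)
    for i in range(n_iterations):
        trial = params.replace(**{k: draws[k][i] for k in names})
        lpi = run_cohort(trial, LPI, scenario)
        obs = run_cohort(trial, OBSERVATION, scenario)
        d_cost[i] = lpi.total_cost - obs.total_cost
        d_qaly[i] = lpi.total_qaly - obs.total_qaly

    return PSAResult(
        scenario_label=scenario.label,
        seed=seed,
        n_iterations=n_iterations,
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        wtp=params.wtp,
        resampled_iterations=resampled,
        draws=pd.DataFrame(draws) if keep_draws else None,
    )


def ceac(result: PSAResult, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: at each willingness-to-pay
    threshold, the fraction of iterations with positive net monetary
    benefit."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    probs = [result.prob_cost_effective(l) for l in grid]
    return pd.DataFrame({"wtp_jpy_per_qaly": grid,
                         "prob_cost_effective": probs})


def ceac_crossing(result: PSAResult, prob: float = 0.5,
                  upper: float = 20_000_000.0, step: float = 10_000.0) -> float:
    """Smallest willingness-to-pay on a fine grid at which the
    acceptability curve reaches ``prob``; inf if it never does."""
    grid = np.arange(0.0, upper + step, step)
    curve = ceac(result, grid)
    hit = curve[curve["prob_cost_effective"] >= prob]
    return float(hit["wtp_jpy_per_qaly"].iloc[0]) if len(hit) else float("inf")
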