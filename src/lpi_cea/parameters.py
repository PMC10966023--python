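"""Model inputs for the angle-closure cost-utility model.

Every number the model consumes lives here: annual transition
probabilities between the angle-closure health states, state utilities,
annual state costs in Japanese Yen (payer perspective, 2022 fee
schedule), and the analysis constants (discount rate, willingness to
pay, exchange rate).  Each input carries its deterministic
sensitivity-analysis range (+/-30% for probabilities, +/-8% for
utilities, +/-20% for costs, 0-4% for the discount rate) and its
probabilistic sensitivity-analysis distribution (beta for probabilities
and utilities, gamma for costs, with SD equal to 10% of the mean, 5%
for utilities).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace as _dc_replace
from pathlib import Path
from typing import Iterator, Mapping

import yaml

__all__ = [
    "Parameter",
    "ParameterSet",
    "ScenarioConfig",
    "SocietalInputs",
    "default_parameters",
    "load_parameters",
    "age_bracket_value",
]

# DSA deviation fractions by parameter kind
_DSA_PROB = 0.30
_DSA_UTIL = 0.08
_DSA_COST = 0.20

# PSA standard deviations as a fraction of the mean
_SD_PROB = 0.10
_SD_UTIL = 0.05
_SD_COST = 0.10


@dataclass(frozen=True)
class Parameter:
    """One model input with its sensitivity-analysis metadata."""

    name: str
    value: float
    dsa_low: float
    dsa_high: float
    psa_family: str  # "beta" | "gamma" | "fixed"
    psa_sd_fraction: float  # 0.0 when fixed
    kind: str  # "probability" | "utility" | "cost" | "constant"

    @property
    def varied_in_dsa(self) -> bool:
        return self.dsa_low != self.dsa_high

    @property
    def varied_in_psa(self) -> bool:
        return self.psa_family != "fixed"

    @property
    def psa_sd(self) -> float:
        return self.psa_sd_fraction * self.value


def _prob(name: str, value: float, *, fixed: bool = False) -> Parameter:
    if fixed:
        return Parameter(name, value, value, value, "fixed", 0.0, "probability")
    return Parameter(
        name, value, value * (1 - _DSA_PROB), value * (1 + _DSA_PROB),
        "beta", _SD_PROB, "probability",
    )


def _util(name: str, value: float, *, fixed: bool = False) -> Parameter:
    if fixed:
        return Parameter(name, value, value, value, "fixed", 0.0, "utility")
    return Parameter(
        name, value, value * (1 - _DSA_UTIL), value * (1 + _DSA_UTIL),
        "beta", _SD_UTIL, "utility",
    )


def _cost(name: str, value: float) -> Parameter:
    return Parameter(
        name, value, value * (1 - _DSA_COST), value * (1 + _DSA_COST),
        "gamma", _SD_COST, "cost",
    )


def _const(name: str, value: float, low: float | None = None,
           high: float | None = None) -> Parameter:
    if low is None:
        low = high = value
    return Parameter(name, value, low, high, "fixed", 0.0, "constant")


def _default_registry() -> tuple[Parameter, ...]:
    return (
        # annual transition probabilities (entered as fractions)
        _prob("p_pacs_pac_lpi", 0.0117),
        _prob("p_pacs_pac_obs", 0.0218),
        _prob("p_pac_pacg_lpi", 0.00146),
        _prob("p_pac_pacg_obs", 0.0034),
        _prob("p_pacg_uniblind", 0.0046),
        _prob("p_uni_biblind", 0.0387),
        _prob("p_pacs_aacc_obs", 0.00097),
        _prob("p_aacc_pacs_lpiopen", 1.0, fixed=True),
        _prob("p_pacg_trab_40_49", 0.0088),
        _prob("p_pacg_trab_50_59", 0.0063),
        # utilities (QALY weight per year in state)
        _util("u_pacs", 1.0, fixed=True),
        _util("u_pac", 1.0, fixed=True),
        _util("u_aacc", 0.99, fixed=True),
        _util("u_pacg", 0.75),
        _util("u_trab", 0.74),
        _util("u_uniblind", 0.47),
        _util("u_biblind", 0.26),
        # annual costs, JPY, payer perspective
        _cost("c_pacs_lpi_y1", 98_393),
        _cost("c_pacs_obs_y1", 19_560),
        _cost("c_pacs_lpi_follow", 23_780),
        _cost("c_pacs_obs_follow", 22_180),
        _cost("c_pac_y1", 171_259),
        _cost("c_pac_follow", 23_780),
        _cost("c_pacg_40_49", 48_545),
        _cost("c_pacg_50_59", 47_553),
        _cost("c_uniblind_40_49", 46_645),
        _cost("c_uniblind_50_59", 45_653),
        _cost("c_biblind_40_49", 44_745),
        _cost("c_biblind_50_59", 43_753),
        _cost("c_aacc", 107_167),
        _cost("c_trab", 697_008),
        # analysis constants
        _const("discount_rate", 0.02, 0.0, 0.04),
        _const("wtp", 5_000_000),
        _const("jpy_per_gbp", 160),
        _const("trab_utility_loss", 0.007),
    )


@dataclass(frozen=True)
class SocietalInputs:
    """User-supplied inputs for the societal perspective.

    Only the travel cost per visit and the unilateral-blindness fraction
    of indirect costs have published defaults; the annual indirect cost
    of bilateral blindness and the visit schedule must be supplied.
    """

    indirect_cost_biblind: float
    visits_per_state: Mapping[str, float]
    uniblind_fraction: float = 0.30
    travel_cost_per_visit: float = 4_547.0

    def indirect_cost(self, state: str) -> float:
        base = state.split("_y1")[0]
        if base == "BIBLIND":
            return self.indirect_cost_biblind
        if base == "UNIBLIND":
            return self.uniblind_fraction * self.indirect_cost_biblind
        return 0.0

    def travel_cost(self, state: str) -> float:
        return self.travel_cost_per_visit * float(
            self.visits_per_state.get(state, 0.0))

    def to_dict(self) -> dict:
        return {
            "indirect_cost_biblind": self.indirect_cost_biblind,
            "visits_per_state": dict(self.visits_per_state),
            "uniblind_fraction": self.uniblind_fraction,
            "travel_cost_per_visit": self.travel_cost_per_visit,
        }


class ParameterSet:
    """Immutable collection of model inputs with attribute access.

    ``ps.c_trab`` returns the numeric value; ``ps.get("c_trab")``
    returns the full :class:`Parameter` with its DSA range and PSA
    specification.
    """

    def __init__(self, registry: tuple[Parameter, ...],
                 societal: SocietalInputs | None = None) -> None:
        object.__setattr__(self, "_registry", dict((p.name, p) for p in registry))
        object.__setattr__(self, "_societal", societal)
        self.validate()

    # -- access ------------------------------------------------------------

    def __getattr__(self, name: str) -> float:
        reg = object.__getattribute__(self, "_registry")
        if name in reg:
            return reg[name].value
        raise AttributeError(f"unknown parameter {name!r}")

    def __setattr__(self, name: str, value) -> None:
        raise AttributeError("ParameterSet is immutable; use replace()")

    def get(self, name: str) -> Parameter:
        return self._registry[name]

    def names(self) -> tuple[str, ...]:
        return tuple(self._registry)

    def __iter__(self) -> Iterator[Parameter]:
        return iter(self._registry.values())

    @property
    def societal(self) -> SocietalInputs | None:
        return self._societal

    # -- derived -----------------------------------------------------------

    def replace(self, societal: SocietalInputs | None = None,
                **overrides: float) -> "ParameterSet":
        """Return a new set with named values overridden (metadata kept)."""
        reg = []
        for p in self:
            if p.name in overrides:
                v = float(overrides.pop(p.name))
                low, high = p.dsa_low, p.dsa_high
                # keep the DSA interval invariant low <= value <= high
                if p.varied_in_dsa:
                    low, high = min(low, v), max(high, v)
                else:
                    low = high = v
                reg.append(_dc_replace(p, value=v, dsa_low=low, dsa_high=high))
            else:
                reg.append(p)
        if overrides:
            raise ValueError(
                "unknown parameter(s): " + ", ".join(sorted(overrides)))
        return ParameterSet(tuple(reg), societal or self._societal)

    def with_parameter_at(self, name: str, value: float) -> "ParameterSet":
        """One-way DSA excursion: a single parameter moved, all else default."""
        return self.replace(**{name: value})

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        errs = []
        for p in self:
            if p.kind == "probability" and not 0.0 <= p.value <= 1.0:
                errs.append(f"{p.name}={p.value} outside [0, 1]")
            if p.kind == "utility" and not 0.0 <= p.value <= 1.0:
                errs.append(f"{p.name}={p.value} outside [0, 1]")
            if p.kind == "cost" and p.value < 0:
                errs.append(f"{p.name}={p.value} negative")
            if not p.dsa_low <= p.value <= p.dsa_high:
                errs.append(f"{p.name}: DSA range [{p.dsa_low}, {p.dsa_high}] "
                            f"does not bracket {p.value}")
        reg = self._registry
        if reg["discount_rate"].value < 0:
            errs.append("discount_rate negative")
        # exit probabilities must not exceed 1 for any state
        exits = {
            "PACS (observation)": reg["p_pacs_pac_obs"].value
            + reg["p_pacs_aacc_obs"].value,
            "PACS (LPI)": reg["p_pacs_pac_lpi"].value,
            "PAC (observation)": reg["p_pac_pacg_obs"].value,
            "PACG": reg["p_pacg_uniblind"].value,
            "unilateral blindness": reg["p_uni_biblind"].value,
        }
        for state, total in exits.items():
            if total > 1.0:
                errs.append(f"exit probabilities from {state} sum to {total} > 1")
        if errs:
            raise ValueError("invalid parameters: " + "; ".join(errs))

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        d = {p.name: p.value for p in self}
        if self._societal is not None:
            d["societal"] = self._societal.to_dict()
        return d

    def to_frame(self):
        """Resolved set as a DataFrame (one row per parameter)."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "name": p.name,
                    "value": p.value,
                    "dsa_low": p.dsa_low,
                    "dsa_high": p.dsa_high,
                    "psa_family": p.psa_family,
                    "psa_sd_fraction": p.psa_sd_fraction,
                    "kind": p.kind,
                }
                for p in self
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def __eq__(self, other) -> bool:
        return (isinstance(other, ParameterSet)
                and self._registry == other._registry
                and self._societal == other._societal)


def default_parameters() -> ParameterSet:
    """The complete default input set with DSA ranges and PSA specs."""
    return ParameterSet(_default_registry())


def load_parameters(source) -> ParameterSet:
    """Build a ParameterSet from defaults plus overrides.

    ``source`` may be a mapping, a YAML/JSON file path, or None/empty for
    pure defaults.  Unknown keys raise; out-of-range values raise from
    validation.  An optional ``societal`` block supplies the
    societal-perspective inputs.
    """
    if source is None:
        return default_parameters()
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        doc = (json.loads(text) if str(source).endswith(".json")
               else yaml.safe_load(text)) or {}
    elif isinstance(source, Mapping):
        doc = dict(source)
    else:
        raise TypeError(f"cannot load parameters from {type(source).__name__}")

    societal = None
    if "societal" in doc:
        block = dict(doc.pop("societal"))
        societal = SocietalInputs(
            indirect_cost_biblind=float(block.pop("indirect_cost_biblind")),
            visits_per_state=dict(block.pop("visits_per_state", {})),
            uniblind_fraction=float(block.pop("uniblind_fraction", 0.30)),
            travel_cost_per_visit=float(block.pop("travel_cost_per_visit", 4547.0)),
        )
        if block:
            raise ValueError("unknown societal key(s): "
                             + ", ".join(sorted(block)))
    return default_parameters().replace(societal=societal, **doc)


@dataclass(frozen=True)
class ScenarioConfig:
    """Cohort entry/exit ages; the horizon is exit - entry + 1 yearly cycles."""

    entry_age: int
    exit_age: int
    label: str = ""
    perspective: str = "payer"

    def __post_init__(self) -> None:
        if self.entry_age < 40:
            raise ValueError("entry_age must be >= 40")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.perspective not in ("payer", "societal"):
            raise ValueError(f"unknown perspective {self.perspective!r}")
        if not self.label:
            object.__setattr__(
                self, "label",
                f"{self.entry_age}-{self.exit_age} ({self.horizon}-year horizon)")

    @property
    def horizon(self) -> int:
        return self.exit_age - self.entry_age + 1

    def age_at(self, cycle: int) -> int:
        return self.entry_age + cycle


_BRACKET_FAMILIES = {
    "trab_prob": ("p_pacg_trab_40_49", "p_pacg_trab_50_59"),
    "pacg_cost": ("c_pacg_40_49", "c_pacg_50_59"),
    "uniblind_cost": ("c_uniblind_40_49", "c_uniblind_50_59"),
    "biblind_cost": ("c_biblind_40_49", "c_biblind_50_59"),
}


def age_bracket_value(params: ParameterSet, family: str, age: float) -> float:
    """Age-bracketed lookup: [40, 50) uses the 40-49 value, ages >= 50
    (including 60+) use the 50-59 value."""
    if family not in _BRACKET_FAMILIES:
        raise KeyError(f"unknown bracket family {family!r}")
    if age < 40:
        raise ValueError(f"age {age} below model entry age 40")
    lo, hi = _BRACKET_FAMILIES[family]
    return getattr(params, lo if age < 50 else hi)
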