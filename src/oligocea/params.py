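"""Model parameters: domain types, the built-in base case, and config I/O.

The model compares three local treatment strategies for liver metastases of
oligometastatic colorectal cancer — hepatic resection (surgery),
radiofrequency ablation (RFA) and microwave ablation (MWA) — in a decision
tree (30-day short-run model) composed with a four-state annual-cycle Markov
cohort model run to a maximum age of 100.

All monetary amounts are nominal 2018 USD; no inflation adjustment is
applied. Utilities are preference weights in [0, 1] (1 = perfect health,
0 = death).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import yaml

__all__ = [
    "HealthState",
    "StrategyParams",
    "ModelSettings",
    "ModelConfig",
    "ValidationError",
    "builtin_base_case",
    "load_config",
    "save_config",
    "total_treatment_cost",
    "STRATEGY_ORDER",
]

#: Canonical strategy ordering used for all deterministic output.
STRATEGY_ORDER = ("surgery", "RFA", "MWA")


class ValidationError(ValueError):
    """A parameter set violates a model invariant."""


class HealthState(enum.IntEnum):
    """The four Markov health states. ``DEATH`` is absorbing."""

    NO_RECURRENCE = 0
    HEPATIC_RECURRENCE = 1
    OTHER_RECURRENCE = 2
    DEATH = 3


def _check_prob(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value)):
        raise ValidationError(f"{name} must be a finite number, got {value!r}")
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must be in [0, 1], got {value}")


def _check_nonneg(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value)):
        raise ValidationError(f"{name} must be a finite number, got {value!r}")
    if value < 0:
        raise ValidationError(f"{name} must be >= 0, got {value}")


@dataclass(frozen=True)
class StrategyParams:
    """All strategy-specific inputs for one treatment arm.

    Parameters
    ----------
    name
        Strategy label, conventionally one of ``surgery``/``RFA``/``MWA``.
    p_success_first
        Probability of complete resection/ablation in the first session.
    acute_procedure_cost
        Procedure cost (USD), excluding the hospital stay.
    hospital_days
        Length of hospital stay in days (charged at the shared per-day cost).
    qol_first_month
        Utility measured one month after treatment; applied as the
        first-cycle reward (see :mod:`oligocea.engine`).
    mortality_year1
        All-cause probability of death during the first year after
        treatment; replaces background mortality in cycle 1.
    p_hepatic_recurrence
        Annual probability of hepatic-only recurrence while recurrence-free.
    p_other_recurrence
        Annual probability of any other (non-hepatic) recurrence.
    """

    name: str
    p_success_first: float
    acute_procedure_cost: float
    hospital_days: int
    qol_first_month: float
    mortality_year1: float
    p_hepatic_recurrence: float
    p_other_recurrence: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("strategy name must be non-empty")
        for f in ("p_success_first", "qol_first_month", "mortality_year1",
                  "p_hepatic_recurrence", "p_other_recurrence"):
            _check_prob(f"{self.name}.{f}", getattr(self, f))
        _check_nonneg(f"{self.name}.acute_procedure_cost", self.acute_procedure_cost)
        if not (isinstance(self.hospital_days, int) and self.hospital_days >= 0):
            raise ValidationError(
                f"{self.name}.hospital_days must be a nonnegative integer, "
                f"got {self.hospital_days!r}"
            )
        outgoing = (self.mortality_year1 + self.p_hepatic_recurrence
                    + self.p_other_recurrence)
        if outgoing > 1.0 + 1e-12:
            raise ValidationError(
                f"{self.name}: cycle-1 outgoing probability from the "
                f"no-recurrence state sums to {outgoing:.6g} > 1"
            )


@dataclass(frozen=True)
class ModelSettings:
    """Shared economic and structural settings.

    The three ``*_convention`` style flags select reward-accrual conventions
    the source material leaves open; the defaults are the set under which
    the model reproduces its published base-case totals (see
    ``docs/methods.md``).
    """

    age_start: int = 73
    age_max: int = 100
    discount_rate: float = 0.03
    wtp: float = 100_000.0
    cost_per_hospital_day: float = 2_424.0
    cost_no_recurrence_per_cycle: float = 855.0
    cost_recurrence_per_cycle: float = 3_935.0
    utility_no_recurrence: float = 1.0
    utility_hepatic_recurrence: float = 0.65
    utility_other_recurrence: float = 0.19
    utility_death: float = 0.0
    p_death_hepatic_recurrence: float = 0.12
    p_death_other_recurrence: float = 0.05
    p_success_second_session: float = 1.0
    #: If True, death from a recurrence state combines the state-specific
    #: probability with background qx as independent competing risks
    #: (1 - (1-qx)(1-q_state)); if False the flat state probability is used.
    recurrence_mortality_compounds_background: bool = False
    #: "full_year": qol_first_month is the whole first cycle's utility.
    #: "one_month_blend": first cycle accrues 1/12 at qol_first_month and
    #: 11/12 at the no-recurrence utility.
    first_cycle_utility: str = "full_year"
    #: Half-cycle correction: accrue rewards on the average of start- and
    #: end-of-cycle occupancy rather than start-of-cycle membership.
    half_cycle_correction: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValidationError(
                f"discount_rate must be in [0, 1), got {self.discount_rate}")
        if not self.age_start < self.age_max:
            raise ValidationError(
                f"age_start ({self.age_start}) must be < age_max ({self.age_max})")
        for f in ("utility_no_recurrence", "utility_hepatic_recurrence",
                  "utility_other_recurrence", "utility_death",
                  "p_death_hepatic_recurrence", "p_death_other_recurrence",
                  "p_success_second_session"):
            _check_prob(f, getattr(self, f))
        if self.utility_death != 0.0:
            raise ValidationError("utility_death must be 0")
        for f in ("wtp", "cost_per_hospital_day", "cost_no_recurrence_per_cycle",
                  "cost_recurrence_per_cycle"):
            _check_nonneg(f, getattr(self, f))
        if self.first_cycle_utility not in ("full_year", "one_month_blend"):
            raise ValidationError(
                "first_cycle_utility must be 'full_year' or 'one_month_blend', "
                f"got {self.first_cycle_utility!r}")

    @property
    def n_cycles(self) -> int:
        """Horizon in annual cycles (age_max - age_start)."""
        return self.age_max - self.age_start

    def state_utilities(self) -> tuple[float, float, float, float]:
        return (self.utility_no_recurrence, self.utility_hepatic_recurrence,
                self.utility_other_recurrence, self.utility_death)

    def state_costs(self) -> tuple[float, float, float, float]:
        return (self.cost_no_recurrence_per_cycle,
                self.cost_recurrence_per_cycle,
                self.cost_recurrence_per_cycle, 0.0)


@dataclass(frozen=True)
class ModelConfig:
    """A complete, validated model configuration."""

    settings: ModelSettings
    strategies: tuple[StrategyParams, ...]
    lifetable_source: str | None = None

    def __post_init__(self) -> None:
        names = [s.name for s in self.strategies]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate strategy names: {names}")
        if len(names) == 0:
            raise ValidationError("at least one strategy is required")

    def __iter__(self) -> Iterator[StrategyParams]:
        return iter(self.strategies)

    def strategy(self, name: str) -> StrategyParams:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(name)


def total_treatment_cost(strategy: StrategyParams,
                         settings: ModelSettings) -> float:
    """Total cost of one treatment session (USD).

    Procedure cost plus the hospital stay charged at the shared per-day
    rate: ``acute_procedure_cost + hospital_days * cost_per_hospital_day``.
    """
    return (strategy.acute_procedure_cost
            + strategy.hospital_days * settings.cost_per_hospital_day)


def builtin_base_case() -> ModelConfig:
    """The built-in base-case parameter set.

    Efficacy, cost and quality-of-life inputs for surgery, RFA and MWA in
    resectable colorectal liver metastases amenable to all three
    modalities: 2018 US Medicare procedure costs, a USD 2,424/day hospital
    rate, literature-based recurrence and mortality probabilities, a 3%
    annual discount rate and a willingness to pay of USD 100,000/QALY.
    """
    return ModelConfig(
        settings=ModelSettings(),
        strategies=(
            StrategyParams("surgery", p_success_first=0.99,
                           acute_procedure_cost=2_421.0, hospital_days=7,
                           qol_first_month=0.70, mortality_year1=0.0825,
                           p_hepatic_recurrence=0.025, p_other_recurrence=0.05),
            StrategyParams("RFA", p_success_first=0.93,
                           acute_procedure_cost=1_493.0, hospital_days=4,
                           qol_first_month=0.95, mortality_year1=0.06,
                           p_hepatic_recurrence=0.077, p_other_recurrence=0.05),
            StrategyParams("MWA", p_success_first=0.97,
                           acute_procedure_cost=1_493.0, hospital_days=4,
                           qol_first_month=0.95, mortality_year1=0.055,
                           p_hepatic_recurrence=0.04, p_other_recurrence=0.05),
        ),
    )


# -- config (de)serialisation ------------------------------------------------

def _config_to_dict(config: ModelConfig) -> dict:
    d = {
        "settings": dataclasses.asdict(config.settings),
        "strategies": [dataclasses.asdict(s) for s in config.strategies],
    }
    if config.lifetable_source is not None:
        d["lifetable_source"] = config.lifetable_source
    return d


def _config_from_dict(d: dict, where: str = "<config>") -> ModelConfig:
    if not isinstance(d, dict):
        raise ValidationError(f"{where}: top level must be a mapping")
    for key in ("settings", "strategies"):
        if key not in d:
            raise ValidationError(f"{where}: missing required key {key!r}")
    try:
        settings = ModelSettings(**d["settings"])
    except TypeError as exc:
        raise ValidationError(f"{where}: settings: {exc}") from exc
    strategies = []
    for i, sd in enumerate(d["strategies"]):
        try:
            strategies.append(StrategyParams(**sd))
        except TypeError as exc:
            raise ValidationError(f"{where}: strategies[{i}]: {exc}") from exc
    return ModelConfig(settings=settings, strategies=tuple(strategies),
                       lifetable_source=d.get("lifetable_source"))


def load_config(path: str | Path) -> ModelConfig:
    """Read and validate a model configuration from YAML or JSON.

    The schema mirrors the dataclass field names exactly; see the bundled
    ``data/base_case.yaml`` for a complete example. Raises
    :class:`ValidationError` on any missing key or invariant violation.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return _config_from_dict(data, where=str(path))


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration to YAML (or JSON if the path ends in .json)."""
    path = Path(path)
    d = _config_to_dict(config)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
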