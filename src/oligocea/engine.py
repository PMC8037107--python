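"""Markov cohort engine: expected discounted lifetime cost and QALYs.

One strategy is evaluated as a 30-day short-run treatment model composed
with a four-state annual-cycle Markov cohort model run from ``age_start``
to ``age_max``. States: no recurrence, hepatic-only recurrence, any other
recurrence, death (absorbing); recurrence states are mutually absorbing —
there is no cross-transition and no return to the recurrence-free state.

Conventions (all selected in :class:`~oligocea.params.ModelSettings`):

* Cycle ``t`` (t = 1..N, covering year t-1 -> t) is discounted by
  ``(1+r)**-(t-1)``; the short-run acute cost is undiscounted at time 0.
* With half-cycle correction (default) rewards accrue on the average of
  start- and end-of-cycle occupancy; otherwise on start-of-cycle
  membership.
* In cycle 1 the strategy's observed all-cause 1-year mortality replaces
  background mortality; from cycle 2 on, background qx at the attained age
  (``age_start + cycle - 1``) applies.
* Death from a recurrence state uses the state-specific annual
  probability, optionally compounded with background qx as independent
  competing risks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .lifetable import LifeTable
from .params import (HealthState, ModelConfig, ModelSettings, StrategyParams,
                     ValidationError, total_treatment_cost)

__all__ = ["CohortTrace", "StrategyOutcome", "short_run",
           "build_transition_matrix", "run_cohort", "run_all"]

N_STATES = 4


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle cohort occupancy and discounted reward increments.

    Row ``t`` of ``occupancy`` is the state distribution at the *start* of
    cycle ``t+1`` (row 0 is the initial cohort); ``cost_increments`` and
    ``qaly_increments`` hold one discounted increment per cycle.
    """

    ages: np.ndarray
    occupancy: np.ndarray
    cost_increments: np.ndarray
    qaly_increments: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        n = len(self.cost_increments)
        return pd.DataFrame({
            "cycle": np.arange(1, n + 1),
            "age": self.ages,
            "occ_no_recurrence": self.occupancy[:n, HealthState.NO_RECURRENCE],
            "occ_hepatic": self.occupancy[:n, HealthState.HEPATIC_RECURRENCE],
            "occ_other": self.occupancy[:n, HealthState.OTHER_RECURRENCE],
            "occ_death": self.occupancy[:n, HealthState.DEATH],
            "cost_increment": self.cost_increments,
            "qaly_increment": self.qaly_increments,
        })

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class StrategyOutcome:
    """Expected discounted lifetime cost (USD) and QALYs for one strategy."""

    strategy: str
    expected_cost: float
    expected_qaly: float
    trace: CohortTrace


def short_run(strategy: StrategyParams,
              settings: ModelSettings) -> tuple[float, float]:
    """The 30-day treatment model: (expected acute cost, first-month utility).

    An incomplete first session (probability ``1 - p_success_first``) is
    followed by a second session assumed successful, which repeats the full
    treatment cost. All patients therefore enter the Markov model
    treatment-complete.
    """
    tc = total_treatment_cost(strategy, settings)
    expected_cost = tc * (1.0 + (1.0 - strategy.p_success_first))
    return expected_cost, strategy.qol_first_month


def build_transition_matrix(strategy: StrategyParams,
                            settings: ModelSettings,
                            table: LifeTable,
                            cycle: int,
                            age: int) -> np.ndarray:
    """The 4x4 row-stochastic transition matrix for one annual cycle.

    From the no-recurrence state the competing transitions are death
    (strategy 1-year mortality in cycle 1, background qx thereafter),
    hepatic recurrence and other recurrence, with the residual staying.
    """
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle}")
    qx = table.qx_at(age)
    d = strategy.mortality_year1 if cycle == 1 else qx
    p_hep = strategy.p_hepatic_recurrence
    p_oth = strategy.p_other_recurrence
    out = d + p_hep + p_oth
    if out > 1.0 + 1e-12:
        raise ValidationError(
            f"{strategy.name}, cycle {cycle}, age {age}: outgoing "
            f"probability from no-recurrence sums to {out:.6g} > 1")
    if settings.recurrence_mortality_compounds_background:
        d_hep = 1.0 - (1.0 - qx) * (1.0 - settings.p_death_hepatic_recurrence)
        d_oth = 1.0 - (1.0 - qx) * (1.0 - settings.p_death_other_recurrence)
    else:
        d_hep = settings.p_death_hepatic_recurrence
        d_oth = settings.p_death_other_recurrence
    stay = 1.0 - out
    return np.array([
        [stay, p_hep, p_oth, d],
        [0.0, 1.0 - d_hep, 0.0, d_hep],
        [0.0, 0.0, 1.0 - d_oth, d_oth],
        [0.0, 0.0, 0.0, 1.0],
    ])


def run_cohort(strategy: StrategyParams,
               settings: ModelSettings,
               table: LifeTable) -> StrategyOutcome:
    """Evaluate one strategy's expected discounted lifetime cost and QALYs."""
    n = settings.n_cycles
    r = settings.discount_rate
    acute_cost, qol1 = short_run(strategy, settings)

    utilities = np.array(settings.state_utilities())
    costs = np.array(settings.state_costs())

    occ = np.zeros((n + 1, N_STATES))
    occ[0, HealthState.NO_RECURRENCE] = 1.0
    cost_inc = np.zeros(n)
    qaly_inc = np.zeros(n)
    ages = settings.age_start + np.arange(n)

    for t in range(1, n + 1):
        p = build_transition_matrix(strategy, settings, table, t,
                                    int(ages[t - 1]))
        occ[t] = occ[t - 1] @ p
        u = utilities.copy()
        if t == 1:
            if settings.first_cycle_utility == "full_year":
                u[HealthState.NO_RECURRENCE] = qol1
            else:  # one_month_blend
                u[HealthState.NO_RECURRENCE] = (
                    qol1 / 12.0 + 11.0 / 12.0 * settings.utility_no_recurrence)
        w = 0.5 * (occ[t - 1] + occ[t]) if settings.half_cycle_correction \
            else occ[t - 1]
        disc = (1.0 + r) ** -(t - 1)
        qaly_inc[t - 1] = disc * float(w @ u)
        cost_inc[t - 1] = disc * float(w @ costs)

    trace = CohortTrace(ages=ages, occupancy=occ,
                        cost_increments=cost_inc, qaly_increments=qaly_inc)
    return StrategyOutcome(strategy=strategy.name,
                           expected_cost=acute_cost + float(cost_inc.sum()),
                           expected_qaly=float(qaly_inc.sum()),
                           trace=trace)


def run_all(config: ModelConfig, table: LifeTable) -> list[StrategyOutcome]:
    """Evaluate every strategy in the config, in config order."""
    return [run_cohort(s, config.settings, table) for s in config.strategies]
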