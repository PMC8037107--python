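"""Synthetic inputs: life tables, random configurations, microsim oracle.

The model needs an annual background-mortality table. No machine-readable
table ships with the source data, so this module generates a synthetic
one from a Gompertz hazard law — mortality rising exponentially with age,
the standard first-order description of adult human mortality:

    qx(age) = 1 - exp(-a * e^(b * age))

The default parameters are calibrated so that remaining (undiscounted)
life expectancy at age 73 is about 13 years, the ballpark of the 2014 US
period life table at the model's base-case starting age. The generated
table is a synthetic stand-in, not transcribed vital statistics.

The module also provides a patient-level microsimulation that applies the
identical short-run and Markov rules by sampling individual trajectories.
Agreement between its means and the cohort engine (within Monte Carlo
error) is the package's primary correctness oracle for the engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import build_transition_matrix, short_run
from .lifetable import LifeTable
from .params import (HealthState, ModelConfig, ModelSettings, StrategyParams,
                     STRATEGY_ORDER)

__all__ = ["GompertzSpec", "MicrosimResult", "DEFAULT_GOMPERTZ",
           "generate_lifetable", "microsim_oracle", "random_config"]


@dataclass(frozen=True)
class GompertzSpec:
    """Gompertz hazard: h(age) = a * e^(b * age), annualised to qx."""

    a: float
    b: float
    age_min: int = 0
    age_max: int = 100

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"baseline hazard a must be > 0, got {self.a}")
        if self.b < 0:
            raise ValueError(f"slope b must be >= 0, got {self.b}")
        if self.age_min > self.age_max:
            raise ValueError("age_min must be <= age_max")

    def qx(self, age: float) -> float:
        """Closed-form annual death probability, clamped at 1."""
        return min(1.0, 1.0 - math.exp(-self.a * math.exp(self.b * age)))


#: Calibrated so remaining life expectancy at age 73 is ~13.0 years.
DEFAULT_GOMPERTZ = GompertzSpec(a=6.065e-5, b=0.085)


def generate_lifetable(spec: GompertzSpec = DEFAULT_GOMPERTZ) -> LifeTable:
    """Deterministic synthetic life table from the Gompertz closed form.

    qx values are rounded to 6 decimals so that a CSV round trip is exact.
    """
    ages = np.arange(spec.age_min, spec.age_max + 1)
    q = np.round([spec.qx(a) for a in ages], 6)
    return LifeTable(age_min=spec.age_min, qx=q)


@dataclass(frozen=True)
class MicrosimResult:
    """Patient-level simulation means with Monte Carlo standard errors."""

    n_patients: int
    seed: int
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float


def microsim_oracle(strategy: StrategyParams, settings: ModelSettings,
                    table: LifeTable, n_patients: int,
                    seed: int) -> MicrosimResult:
    """Simulate individual patients under the exact cohort-model rules.

    Each patient gets an independent random stream derived from the master
    seed, so results do not depend on evaluation order. The second
    treatment session is sampled (probability ``1 - p_success_first``) and
    repeats the full treatment cost; annual transitions are sampled from
    the same matrices the cohort engine builds; discounted rewards accrue
    under the same first-cycle and half-cycle conventions.
    """
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    n = settings.n_cycles
    r = settings.discount_rate
    _, qol1 = short_run(strategy, settings)
    from .params import total_treatment_cost
    tc = total_treatment_cost(strategy, settings)

    utilities = np.array(settings.state_utilities())
    state_costs = np.array(settings.state_costs())
    disc = (1.0 + r) ** -np.arange(n)

    # Transition matrices are patient-independent: build cumulative rows once.
    cum_rows = []  # cum_rows[t][state] = cumulative transition probabilities
    u_by_cycle = np.tile(utilities, (n, 1))
    if settings.first_cycle_utility == "full_year":
        u_by_cycle[0, HealthState.NO_RECURRENCE] = qol1
    else:
        u_by_cycle[0, HealthState.NO_RECURRENCE] = (
            qol1 / 12.0 + 11.0 / 12.0 * settings.utility_no_recurrence)
    for t in range(1, n + 1):
        p = build_transition_matrix(strategy, settings, table, t,
                                    settings.age_start + t - 1)
        cum_rows.append(np.cumsum(p, axis=1))

    hcc = settings.half_cycle_correction
    dead = int(HealthState.DEATH)
    costs = np.empty(n_patients)
    qalys = np.empty(n_patients)
    streams = np.random.SeedSequence(seed).spawn(n_patients)
    for i in range(n_patients):
        rng = np.random.default_rng(streams[i])
        draws = rng.random(n + 1)
        cost = tc + (tc if draws[0] < 1.0 - strategy.p_success_first else 0.0)
        qaly = 0.0
        state = int(HealthState.NO_RECURRENCE)
        for t in range(n):
            if state == dead:
                break
            nxt = int(np.searchsorted(cum_rows[t][state], draws[t + 1],
                                      side="right"))
            nxt = min(nxt, dead)
            if hcc:
                qaly += disc[t] * 0.5 * (u_by_cycle[t, state]
                                         + u_by_cycle[t, nxt])
                cost += disc[t] * 0.5 * (state_costs[state] + state_costs[nxt])
            else:
                qaly += disc[t] * u_by_cycle[t, state]
                cost += disc[t] * state_costs[state]
            state = nxt
        costs[i] = cost
        qalys[i] = qaly
    se = 1.0 / math.sqrt(n_patients)
    return MicrosimResult(
        n_patients=n_patients, seed=seed,
        mean_cost=float(costs.mean()), mean_qaly=float(qalys.mean()),
        se_cost=float(costs.std(ddof=1)) * se if n_patients > 1 else float("nan"),
        se_qaly=float(qalys.std(ddof=1)) * se if n_patients > 1 else float("nan"),
    )


def random_config(seed: int) -> ModelConfig:
    """A random but always-valid configuration for property testing.

    Probabilities are drawn jointly feasible (per-cycle outgoing mass from
    the recurrence-free state stays below 1), costs positive, utilities in
    [0, 1]. Three strategies are produced in the canonical order.
    """
    rng = np.random.default_rng(seed)
    age_start = int(rng.integers(55, 85))
    age_max = int(rng.integers(age_start + 5, 101))
    u_hep = float(rng.uniform(0.2, 0.95))
    settings = ModelSettings(
        age_start=age_start,
        age_max=age_max,
        discount_rate=float(rng.uniform(0.0, 0.08)),
        wtp=float(rng.uniform(20_000, 200_000)),
        cost_per_hospital_day=float(rng.uniform(500, 5_000)),
        cost_no_recurrence_per_cycle=float(rng.uniform(100, 3_000)),
        cost_recurrence_per_cycle=float(rng.uniform(1_000, 10_000)),
        utility_hepatic_recurrence=u_hep,
        utility_other_recurrence=float(rng.uniform(0.05, u_hep)),
        p_death_hepatic_recurrence=float(rng.uniform(0.05, 0.4)),
        p_death_other_recurrence=float(rng.uniform(0.02, 0.3)),
        recurrence_mortality_compounds_background=bool(rng.integers(0, 2)),
        half_cycle_correction=bool(rng.integers(0, 2)),
        first_cycle_utility=("full_year", "one_month_blend")[rng.integers(0, 2)],
    )
    strategies = []
    for name in STRATEGY_ORDER:
        # three outgoing probabilities each < 0.3 => sum < 0.9 < 1
        m1, p_hep, p_oth = rng.uniform(0.0, 0.3, size=3)
        strategies.append(StrategyParams(
            name=name,
            p_success_first=float(rng.uniform(0.5, 1.0)),
            acute_procedure_cost=float(rng.uniform(500, 30_000)),
            hospital_days=int(rng.integers(0, 15)),
            qol_first_month=float(rng.uniform(0.3, 1.0)),
            mortality_year1=float(m1),
            p_hepatic_recurrence=float(p_hep),
            p_other_recurrence=float(p_oth),
        ))
    return ModelConfig(settings=settings, strategies=tuple(strategies))
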