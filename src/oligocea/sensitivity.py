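"""Deterministic starting-age sensitivity sweep.

Re-runs the cohort engine with the starting age overridden across a grid
(default 60-85) and reports expected cost, QALYs and net monetary benefit
per strategy at the configured willingness to pay. Only the starting age
varies; treatment parameters, including the observed 1-year mortality,
are held fixed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .cea import nmb
from .engine import run_all
from .lifetable import LifeTable
from .params import ModelConfig

__all__ = ["AgeSweepResult", "age_sweep"]


@dataclass(frozen=True)
class AgeSweepResult:
    """Long-format records: one row per (starting age, strategy)."""

    table: pd.DataFrame  # columns: age, strategy, cost, qaly, nmb
    wtp: float

    def best_strategy_at(self, age: int) -> str:
        rows = self.table[self.table["age"] == age]
        if rows.empty:
            raise KeyError(f"age {age} not in sweep")
        return str(rows.loc[rows["nmb"].idxmax(), "strategy"])

    def nmb_of(self, age: int, strategy: str) -> float:
        rows = self.table[(self.table["age"] == age)
                          & (self.table["strategy"] == strategy)]
        if rows.empty:
            raise KeyError((age, strategy))
        return float(rows["nmb"].iloc[0])

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def age_sweep(config: ModelConfig, table: LifeTable,
              ages: range | list[int] | None = None) -> AgeSweepResult:
    """Expected cost, QALYs and NMB per strategy for each starting age.

    Default grid: 60-85 inclusive, step 1. Every age must lie below
    ``age_max`` and within the life table's coverage.
    """
    if ages is None:
        ages = range(60, 86)
    settings = config.settings
    records = []
    for age in ages:
        if age >= settings.age_max:
            raise ValueError(
                f"starting age {age} must be below age_max {settings.age_max}")
        cfg = dataclasses.replace(config,
                                  settings=dataclasses.replace(
                                      settings, age_start=int(age)))
        for outcome in run_all(cfg, table):
            records.append({
                "age": int(age),
                "strategy": outcome.strategy,
                "cost": outcome.expected_cost,
                "qaly": outcome.expected_qaly,
                "nmb": nmb(outcome.expected_cost, outcome.expected_qaly,
                           settings.wtp),
            })
    return AgeSweepResult(table=pd.DataFrame.from_records(records),
                          wtp=settings.wtp)
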