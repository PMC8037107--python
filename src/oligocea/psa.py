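"""Probabilistic sensitivity analysis (PSA).

Every uncertain parameter receives a parametric distribution — beta for
probabilities and utilities, gamma for costs — parameterised by method of
moments from its base-case mean and a standard error expressed as a
fraction of the mean (``spread_fraction``, default 20%). Each Monte Carlo
iteration draws one full parameter set and re-evaluates the Markov engine
for all strategies; shared parameters are drawn once per iteration and
reused across strategies (common random numbers), strategy-specific
parameters are drawn per strategy.

Structural constants are never drawn: discount rate, ages, WTP, hospital
days, the second-session success assumption, and any parameter whose mean
sits on the boundary of its support (a utility of exactly 1 or a
probability of 0 has no feasible beta perturbation and stays fixed).

The cost-effectiveness acceptability curve (CEAC) reports, per WTP, the
fraction of iterations in which each strategy attains the maximal net
monetary benefit (ties broken toward lower cost, then input order).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cea import nmb  # noqa: F401  (re-exported companion)
from .engine import run_all
from .lifetable import LifeTable
from .params import ModelConfig, ModelSettings, StrategyParams

__all__ = ["DistributionSpec", "PSAResult", "CEACCurve", "make_distribution",
           "draw_parameters", "run_psa", "ceac"]


@dataclass(frozen=True)
class DistributionSpec:
    """A beta or gamma uncertainty distribution by method of moments.

    beta:  nu = mean(1-mean)/se^2 - 1, alpha = mean*nu, beta = (1-mean)*nu
    gamma: shape = (mean/se)^2, scale = se^2/mean
    """

    family: str
    mean: float
    se: float
    shape_a: float
    shape_b: float

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "beta":
            return float(rng.beta(self.shape_a, self.shape_b))
        return float(rng.gamma(self.shape_a, self.shape_b))


def make_distribution(mean: float, se: float, family: str) -> DistributionSpec:
    """Build a beta or gamma spec from (mean, se) by method of moments."""
    if family == "beta":
        if not 0.0 < mean < 1.0:
            raise ValueError(f"beta requires mean in (0, 1), got {mean}")
        if not 0.0 < se * se < mean * (1.0 - mean):
            raise ValueError(
                f"beta requires 0 < se^2 < mean(1-mean): se={se}, mean={mean}")
        nu = mean * (1.0 - mean) / (se * se) - 1.0
        return DistributionSpec("beta", mean, se, mean * nu, (1.0 - mean) * nu)
    if family == "gamma":
        if mean <= 0 or se <= 0:
            raise ValueError(
                f"gamma requires mean > 0 and se > 0: mean={mean}, se={se}")
        return DistributionSpec("gamma", mean, se,
                                (mean / se) ** 2, se * se / mean)
    raise ValueError(f"unknown family {family!r}")


def _draw(rng: np.random.Generator, mean: float, spread: float,
          family: str) -> float:
    """One method-of-moments draw at a relative spread.

    Gamma parameters use se = spread * mean. Beta parameters use
    se = spread * min(mean, 1 - mean): symmetric under recoding a
    probability as its complement, equal to spread * mean for means up to
    one half, and always feasible — a flat spread * mean is impossible for
    means near 1 (se^2 must stay below mean(1-mean)). Boundary means
    (0 or 1 for beta, 0 for gamma) are degenerate and returned unchanged.
    """
    if family == "beta":
        if mean <= 0.0 or mean >= 1.0:
            return mean
        se = spread * min(mean, 1.0 - mean)
    else:
        if mean <= 0.0:
            return mean
        se = spread * mean
    return make_distribution(mean, se, family).sample(rng)


# Draw order is fixed so that a given seed always yields the same config.
_SHARED_BETA = ("utility_hepatic_recurrence", "utility_other_recurrence",
                "p_death_hepatic_recurrence", "p_death_other_recurrence")
_SHARED_GAMMA = ("cost_per_hospital_day", "cost_no_recurrence_per_cycle",
                 "cost_recurrence_per_cycle")
_STRATEGY_BETA = ("qol_first_month", "mortality_year1", "p_hepatic_recurrence")
_STRATEGY_GAMMA = ("acute_procedure_cost",)


def draw_parameters(config: ModelConfig,
                    spread_fraction: float = 0.2,
                    seed: int | np.random.Generator | None = None,
                    *,
                    draw_success: bool = True) -> ModelConfig:
    """One Monte Carlo draw of the full parameter set.

    ``utility_no_recurrence`` (mean 1) and all structural constants stay
    fixed; the annual non-hepatic recurrence probability is a shared draw
    applied to every strategy (one literature source serves all three).
    ``draw_success`` controls whether first-session success probabilities
    are varied.
    """
    if spread_fraction <= 0:
        raise ValueError(f"spread_fraction must be > 0, got {spread_fraction}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    s = config.settings

    shared: dict[str, float] = {}
    for f in _SHARED_BETA:
        shared[f] = _draw(rng, getattr(s, f), spread_fraction, "beta")
    for f in _SHARED_GAMMA:
        shared[f] = _draw(rng, getattr(s, f), spread_fraction, "gamma")
    # utility_no_recurrence has mean 1: degenerate, kept at 1.
    p_other = _draw(rng, config.strategies[0].p_other_recurrence,
                    spread_fraction, "beta")

    new_settings = dataclasses.replace(s, **shared)
    new_strategies = []
    for strat in config.strategies:
        upd: dict[str, float] = {"p_other_recurrence": p_other}
        if draw_success:
            upd["p_success_first"] = _draw(rng, strat.p_success_first,
                                           spread_fraction, "beta")
        for f in _STRATEGY_BETA:
            upd[f] = _draw(rng, getattr(strat, f), spread_fraction, "beta")
        for f in _STRATEGY_GAMMA:
            upd[f] = _draw(rng, getattr(strat, f), spread_fraction, "gamma")
        new_strategies.append(dataclasses.replace(strat, **upd))
    return ModelConfig(settings=new_settings, strategies=tuple(new_strategies),
                       lifetable_source=config.lifetable_source)


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration strategy outcomes from a PSA run.

    ``costs`` and ``qalys`` are (n_iterations, n_strategies) arrays in the
    configured strategy order.
    """

    n: int
    seed: int
    spread_fraction: float
    strategy_names: tuple[str, ...]
    costs: np.ndarray
    qalys: np.ndarray

    def mean_costs(self) -> dict[str, float]:
        return dict(zip(self.strategy_names, self.costs.mean(axis=0)))

    def mean_qalys(self) -> dict[str, float]:
        return dict(zip(self.strategy_names, self.qalys.mean(axis=0)))

    def to_frame(self) -> pd.DataFrame:
        """Long-format scatter records: iteration, strategy, cost, qaly."""
        n, k = self.costs.shape
        return pd.DataFrame({
            "iteration": np.repeat(np.arange(n), k),
            "strategy": np.tile(np.array(self.strategy_names), n),
            "cost": self.costs.ravel(),
            "qaly": self.qalys.ravel(),
        })

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_psa(config: ModelConfig, table: LifeTable, n: int,
            seed: int, spread_fraction: float = 0.2,
            *, draw_success: bool = True) -> PSAResult:
    """Run ``n`` Monte Carlo iterations of the full model.

    Each iteration draws one parameter set from an independent child
    stream of ``seed`` (so results do not depend on evaluation order) and
    evaluates every strategy with the cohort engine.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    names = tuple(s.name for s in config.strategies)
    k = len(names)
    costs = np.empty((n, k))
    qalys = np.empty((n, k))
    children = np.random.SeedSequence(seed).spawn(n)
    for i in range(n):
        rng = np.random.default_rng(children[i])
        cfg = draw_parameters(config, spread_fraction, rng,
                              draw_success=draw_success)
        for j, outcome in enumerate(run_all(cfg, table)):
            costs[i, j] = outcome.expected_cost
            qalys[i, j] = outcome.expected_qaly
    return PSAResult(n=n, seed=seed, spread_fraction=spread_fraction,
                     strategy_names=names, costs=costs, qalys=qalys)


@dataclass(frozen=True)
class CEACCurve:
    """Cost-effectiveness acceptability curve on a WTP grid.

    ``fractions[i, j]``: fraction of iterations in which strategy ``j``
    has the maximal NMB at ``wtp_grid[i]``. Rows sum to 1.
    """

    wtp_grid: np.ndarray
    strategy_names: tuple[str, ...]
    fractions: np.ndarray

    def fraction_of(self, name: str) -> np.ndarray:
        return self.fractions[:, self.strategy_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        m, k = self.fractions.shape
        return pd.DataFrame({
            "wtp": np.repeat(self.wtp_grid, k),
            "strategy": np.tile(np.array(self.strategy_names), m),
            "probability": self.fractions.ravel(),
        })

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def ceac(result: PSAResult, wtp_grid: np.ndarray | list[float]) -> CEACCurve:
    """Acceptability curve: per WTP, each strategy's win fraction by NMB.

    An iteration is won by the strategy with maximal NMB; exact ties go to
    the cheaper strategy, then to the one listed first.
    """
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    n, k = result.costs.shape
    fractions = np.empty((grid.size, k))
    for i, w in enumerate(grid):
        benefit = w * result.qalys - result.costs
        best = benefit.max(axis=1, keepdims=True)
        candidate = benefit >= best
        # ties -> lower cost; argmin takes the first (input-order) on cost ties
        masked_cost = np.where(candidate, result.costs, np.inf)
        winner = masked_cost.argmin(axis=1)
        fractions[i] = np.bincount(winner, minlength=k) / n
    return CEACCurve(wtp_grid=grid, strategy_names=result.strategy_names,
                     fractions=fractions)
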