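"""Deterministic cost-effectiveness analysis.

Dominance classification, the efficiency frontier with incremental
cost-effectiveness ratios (ICERs), and net monetary benefit (NMB).

Definitions
-----------
Strategy A *dominates* B if A costs no more and yields no fewer QALYs,
with at least one inequality strict. *Extended dominance* removes a
strategy that lies above the line joining two others on the cost-QALY
plane — i.e. whose ICER over the previous frontier member exceeds the next
member's ICER. NMB at willingness to pay ``wtp`` is
``wtp * qalys - cost``; the NMB-maximal strategy at a given WTP is always
on the frontier.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path

from .engine import StrategyOutcome

__all__ = ["Dominance", "StrategyCEA", "FrontierSegment", "CEAResult",
           "nmb", "classify_dominance"]


class Dominance(str, enum.Enum):
    FRONTIER = "frontier"
    DOMINATED = "dominated"
    EXTENDEDLY_DOMINATED = "extendedly_dominated"


@dataclass(frozen=True)
class StrategyCEA:
    strategy: str
    cost: float
    qaly: float
    nmb: float
    dominance: Dominance


@dataclass(frozen=True)
class FrontierSegment:
    """One step on the efficiency frontier with its ICER (USD/QALY).

    ``icer`` is None for the cheapest frontier member (no comparator) and
    infinite when the step adds cost at equal QALYs (a tie kept by the
    configured ordering).
    """

    from_strategy: str | None
    to_strategy: str
    icer: float | None


@dataclass(frozen=True)
class CEAResult:
    strategies: tuple[StrategyCEA, ...]
    frontier: tuple[FrontierSegment, ...]
    wtp: float

    def by_name(self, name: str) -> StrategyCEA:
        for s in self.strategies:
            if s.strategy == name:
                return s
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "wtp": self.wtp,
            "strategies": [
                {"strategy": s.strategy, "cost": s.cost, "qaly": s.qaly,
                 "nmb": s.nmb, "dominance": s.dominance.value}
                for s in self.strategies
            ],
            "frontier": [
                {"from": f.from_strategy, "to": f.to_strategy, "icer": f.icer}
                for f in self.frontier
            ],
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def nmb(cost: float, qaly: float, wtp: float) -> float:
    """Net monetary benefit: ``wtp * qaly - cost`` (USD)."""
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0, got {wtp}")
    return wtp * qaly - cost


def classify_dominance(outcomes: list[StrategyOutcome],
                       wtp: float = 100_000.0) -> CEAResult:
    """Classify strategies and build the efficiency frontier.

    Strict dominance is flagged first; the frontier is then built in order
    of increasing cost and pruned of extendedly dominated members until
    ICERs strictly increase. Ties on identical (cost, QALY) pairs keep the
    strategy listed first in the input order.
    """
    if len(outcomes) < 2:
        raise ValueError("need at least two strategies to compare")
    items = [(o.strategy, o.expected_cost, o.expected_qaly) for o in outcomes]
    order = {name: i for i, (name, _, _) in enumerate(items)}

    flags: dict[str, Dominance] = {}
    for name, c, q in items:
        dominated = False
        for other, oc, oq in items:
            if other == name:
                continue
            if oc <= c and oq >= q and (oc < c or oq > q):
                dominated = True
                break
            # exact tie: keep the first in input order
            if oc == c and oq == q and order[other] < order[name]:
                dominated = True
                break
        flags[name] = Dominance.DOMINATED if dominated else Dominance.FRONTIER

    # Candidate frontier: undominated, sorted by cost (then input order).
    cand = sorted((x for x in items if flags[x[0]] is Dominance.FRONTIER),
                  key=lambda x: (x[1], order[x[0]]))
    # Prune extended dominance: ICERs along the frontier must increase.
    changed = True
    while changed and len(cand) > 2:
        changed = False
        for i in range(1, len(cand) - 1):
            _, c0, q0 = cand[i - 1]
            name, c1, q1 = cand[i]
            _, c2, q2 = cand[i + 1]
            icer_in = _icer(c0, q0, c1, q1)
            icer_out = _icer(c1, q1, c2, q2)
            if icer_out <= icer_in:
                flags[name] = Dominance.EXTENDEDLY_DOMINATED
                del cand[i]
                changed = True
                break

    segments = []
    prev = None
    for name, c, q in cand:
        icer = None if prev is None else _icer(prev[1], prev[2], c, q)
        segments.append(FrontierSegment(
            from_strategy=None if prev is None else prev[0],
            to_strategy=name, icer=icer))
        prev = (name, c, q)

    strategies = tuple(
        StrategyCEA(strategy=name, cost=c, qaly=q, nmb=nmb(c, q, wtp),
                    dominance=flags[name])
        for name, c, q in items)
    return CEAResult(strategies=strategies, frontier=tuple(segments), wtp=wtp)


def _icer(c0: float, q0: float, c1: float, q1: float) -> float:
    dq = q1 - q0
    dc = c1 - c0
    if dq == 0:
        return float("inf") if dc > 0 else float("-inf")
    return dc / dq
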