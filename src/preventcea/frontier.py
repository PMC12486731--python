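"""Incremental cost-effectiveness ratios, dominance and the efficiency frontier.

Strategies are ordered by cost per child. For cost-adjacent strategies the
incremental cost-effectiveness ratio is ``ICER = dC / dE`` with the effect
oriented so that larger is healthier (symptom scores enter with a sign flip).
A strategy is *dominated* when another strategy is at least as cheap and at
least as effective (one strictly); among the survivors a strategy is
*extended dominated* when removing it restores a strictly increasing ICER
sequence along the cost ordering, i.e. a blend of its neighbours buys health
more efficiently. The survivors form the cost-effectiveness frontier, whose
consecutive ICERs strictly increase (the lower convex hull in
(effect, cost) space).

For QALYs, frontier ICERs are judged against the Norwegian cost-effectiveness
threshold range of NOK 275,000-825,000 per QALY; symptom-score ICERs have no
defined threshold and receive no verdict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .measures import MeasureSpec

#: Norwegian severity-dependent willingness-to-pay range, NOK per QALY.
CET_RANGE_NOK: tuple[float, float] = (275_000.0, 825_000.0)


class Classification(Enum):
    FRONTIER = "frontier"
    DOMINATED = "dominated"
    EXTENDED_DOMINATED = "extended_dominated"


def orient_effect(accumulated: float, measure: MeasureSpec) -> float:
    """Accumulated score as an improvement-oriented effect (larger = better):
    negated for symptom scales, identity for utilities/QALYs."""
    return -accumulated if measure.improves_by_decrease else accumulated


@dataclass(frozen=True)
class CEAInput:
    """One strategy's cost per child and accumulated outcome."""

    strategy: str
    cost: float
    accumulated: float
    measure: MeasureSpec

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError(f"{self.strategy}: cost must be non-negative")

    @property
    def effect(self) -> float:
        return orient_effect(self.accumulated, self.measure)


@dataclass(frozen=True)
class Icer:
    """An incremental comparison. ``value`` is NOK per unit of improvement;
    infinite (undefined) when the effects are equal, negative when the extra
    spend buys worse health."""

    delta_cost: float
    delta_effect: float

    @property
    def defined(self) -> bool:
        return self.delta_effect != 0

    @property
    def value(self) -> float:
        if not self.defined:
            return math.inf if self.delta_cost >= 0 else -math.inf
        return self.delta_cost / self.delta_effect


def icer(reference: CEAInput, comparator: CEAInput) -> Icer:
    """ICER of ``comparator`` versus the cheaper ``reference``."""
    if reference.strategy == comparator.strategy:
        raise ValueError(f"cannot compare {reference.strategy} with itself")
    if comparator.cost < reference.cost:
        raise ValueError(
            "comparator must be at least as costly as reference "
            f"({comparator.strategy}: {comparator.cost} < "
            f"{reference.strategy}: {reference.cost})"
        )
    return Icer(comparator.cost - reference.cost, comparator.effect - reference.effect)


@dataclass(frozen=True)
class CEATableRow:
    strategy: str
    cost: float
    accumulated: float
    classification: Classification
    incr_cost: float | None = None  # vs next-cheapest strategy
    incr_effect: float | None = None  # improvement-oriented
    icer: Icer | None = None
    frontier_incr_cost: float | None = None  # vs previous frontier member
    frontier_incr_effect: float | None = None
    frontier_icer: float | None = None


@dataclass(frozen=True)
class FrontierResult:
    measure: MeasureSpec
    frontier: tuple[str, ...]  # strategy codes, cost ascending
    frontier_icers: tuple[float, ...]  # between consecutive frontier members
    cet_range: tuple[float, float] = CET_RANGE_NOK
    cet_verdicts: tuple[str, ...] | None = None  # QALY analyses only
    note: str | None = None


def _sorted_inputs(inputs: list[CEAInput]) -> list[CEAInput]:
    # cost ascending; ties broken by better effect first, then code for
    # determinism
    return sorted(inputs, key=lambda s: (s.cost, -s.effect, s.strategy))


def _dominated(a: CEAInput, others: list[CEAInput]) -> bool:
    # weak dominance: no worse on both axes, strictly better on one
    return any(
        b.cost <= a.cost
        and b.effect >= a.effect
        and (b.cost < a.cost or b.effect > a.effect)
        for b in others
        if b is not a
    )


def classify_and_build_frontier(
    inputs: list[CEAInput],
    cet_range: tuple[float, float] = CET_RANGE_NOK,
) -> tuple[list[CEATableRow], FrontierResult]:
    """Classify every strategy and extract the efficiency frontier.

    Returns the full cost-ordered table (incremental columns computed between
    adjacent rows for *all* strategies, as published) and the frontier with
    its ICERs and, for QALY analyses, threshold verdicts.
    """
    if not inputs:
        raise ValueError("at least one strategy is required")
    codes = [s.strategy for s in inputs]
    if len(set(codes)) != len(codes):
        raise ValueError(f"duplicate strategy codes in input: {sorted(codes)}")
    measures = {s.measure.name for s in inputs}
    if len(measures) != 1:
        raise ValueError(f"inputs mix measures: {sorted(measures)}")
    measure = inputs[0].measure

    order = _sorted_inputs(list(inputs))
    classification: dict[str, Classification] = {}

    # strong/weak dominance; exact (cost, effect) ties collapse onto the first
    # representative in sort order
    seen: set[tuple[float, float]] = set()
    for s in order:
        key = (s.cost, s.effect)
        if _dominated(s, order) or key in seen:
            classification[s.strategy] = Classification.DOMINATED
        seen.add(key)

    survivors = [s for s in order if s.strategy not in classification]

    # extended dominance: drop the middle strategy wherever the ICER sequence
    # fails to increase strictly, until monotone
    while len(survivors) >= 3:
        icers = [icer(a, b).value for a, b in zip(survivors, survivors[1:])]
        for k in range(len(icers) - 1):
            if icers[k] >= icers[k + 1]:
                classification[survivors[k + 1].strategy] = Classification.EXTENDED_DOMINATED
                del survivors[k + 1]
                break
        else:
            break

    for s in survivors:
        classification[s.strategy] = Classification.FRONTIER

    frontier_icers = tuple(icer(a, b).value for a, b in zip(survivors, survivors[1:]))

    rows: list[CEATableRow] = []
    prev: CEAInput | None = None
    prev_frontier: CEAInput | None = None
    for s in order:
        cls = classification[s.strategy]
        inc = icer(prev, s) if prev is not None else None
        f_cost = f_eff = f_icer = None
        if cls is Classification.FRONTIER and prev_frontier is not None:
            f = icer(prev_frontier, s)
            f_cost, f_eff, f_icer = f.delta_cost, f.delta_effect, f.value
        rows.append(
            CEATableRow(
                strategy=s.strategy,
                cost=s.cost,
                accumulated=s.accumulated,
                classification=cls,
                incr_cost=inc.delta_cost if inc else None,
                incr_effect=inc.delta_effect if inc else None,
                icer=inc,
                frontier_incr_cost=f_cost,
                frontier_incr_effect=f_eff,
                frontier_icer=f_icer,
            )
        )
        prev = s
        if cls is Classification.FRONTIER:
            prev_frontier = s

    verdicts: tuple[str, ...] | None = None
    note = None
    if _is_qaly(measure):
        verdicts = tuple(_verdict(v, cet_range) for v in frontier_icers)
    else:
        note = (
            f"no cost-effectiveness threshold is defined for {measure.name}; "
            "verdicts suppressed"
        )
    result = FrontierResult(
        measure=measure,
        frontier=tuple(s.strategy for s in survivors),
        frontier_icers=frontier_icers,
        cet_range=cet_range,
        cet_verdicts=verdicts,
        note=note,
    )
    return rows, result


def _is_qaly(measure: MeasureSpec) -> bool:
    return measure.name == "HRQOL"


def _verdict(icer_value: float, cet_range: tuple[float, float]) -> str:
    low, high = cet_range
    if icer_value <= low:
        return "below_range"
    if icer_value <= high:
        return "within_range"
    return "above_range"


def cet_verdict(
    result: FrontierResult, cet_range: tuple[float, float] | None = None
) -> tuple[str, ...]:
    """Threshold verdicts for a QALY frontier; errors for symptom measures."""
    if not _is_qaly(result.measure):
        raise ValueError(
            f"no cost-effectiveness threshold is defined for {result.measure.name}"
        )
    bounds = cet_range or result.cet_range
    return tuple(_verdict(v, bounds) for v in result.frontier_icers)


def rows_to_frame(rows: list[CEATableRow]) -> pd.DataFrame:
    """Flatten classified rows into a table in cost order."""
    out = []
    for r in rows:
        out.append(
            {
                "strategy": r.strategy,
                "cost": r.cost,
                "incr_cost": r.incr_cost,
                "accumulated": r.accumulated,
                "incr_effect": r.incr_effect,
                "icer": r.icer.value if r.icer is not None and r.icer.defined else None,
                "classification": r.classification.value,
                "frontier_incr_cost": r.frontier_incr_cost,
                "frontier_incr_effect": r.frontier_incr_effect,
                "frontier_icer": r.frontier_icer,
            }
        )
    return pd.DataFrame(out)
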