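"""ICERs, dominance classification and the cost-effectiveness frontier."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from preventcea import (
    CET_RANGE_NOK,
    CEAInput,
    Classification,
    HRQOL,
    MASC,
    SMFQ,
    MeasureSpec,
    cet_verdict,
    classify_and_build_frontier,
    icer,
    orient_effect,
)
from preventcea.frontier import rows_to_frame
from preventcea.measures import BenefitDirection

# Published per-child costs (integer NOK) and accumulated outcomes.
COSTS = {
    "SLN": 5124, "SLF": 6862, "SHN": 8008, "LLN": 8510,
    "SHF": 9746, "LLF": 10_248, "LHN": 11_394, "LHF": 13_132,
}
ACC_MASC = {
    "SLN": 72.98, "SLF": 66.79, "SHN": 72.39, "LLN": 66.89,
    "SHF": 69.65, "LLF": 66.70, "LHN": 70.07, "LHF": 67.22,
}
ACC_SMFQ = {
    "SLN": 11.84, "SLF": 11.25, "SHN": 10.13, "LLN": 9.75,
    "SHF": 10.8, "LLF": 10.21, "LHN": 10.1, "LHF": 10.48,
}
ACC_QALY = {
    "SLN": 0.938, "SLF": 0.949, "SHN": 0.958, "LLN": 0.973,
    "SHF": 0.936, "LLF": 0.969, "LHN": 0.967, "LHF": 0.955,
}


def make_inputs(accumulated: dict, measure) -> list[CEAInput]:
    return [
        CEAInput(code, COSTS[code], accumulated[code], measure)
        for code in COSTS
    ]


def oracle_frontier(points: list[tuple[str, float, float]]) -> set[str]:
    """Brute-force frontier: survivors of pairwise weak dominance that no
    segment between two other survivors undercuts in (effect, cost) space
    (the lower convex hull)."""
    survivors = [
        p
        for p in points
        if not any(
            q[1] <= p[1] and q[2] >= p[2] and (q[1] < p[1] or q[2] > p[2])
            for q in points
            if q is not p
        )
    ]
    frontier = set()
    for p in survivors:
        others = [q for q in survivors if q is not p]
        undercut = False
        for a, b in itertools.combinations(others, 2):
            if a[2] == b[2]:
                continue
            lo, hi = sorted((a[2], b[2]))
            if lo <= p[2] <= hi:
                lam = (p[2] - b[2]) / (a[2] - b[2])
                blended_cost = lam * a[1] + (1 - lam) * b[1]
                if blended_cost < p[1] - 1e-9:
                    undercut = True
                    break
        if not undercut:
            frontier.add(p[0])
    return frontier


class TestOrientEffect:
    def test_symptom_scores_flip_sign(self):
        assert orient_effect(72.98, MASC) == -72.98
        assert orient_effect(11.84, SMFQ) == -11.84

    def test_qalys_identity(self):
        assert orient_effect(0.938, HRQOL) == 0.938

    def test_improvement_between_strategies(self):
        # depressive-symptom improvement going from cheapest to long format
        improvement = orient_effect(9.75, SMFQ) - orient_effect(11.84, SMFQ)
        assert improvement == pytest.approx(2.09)


class TestIcer:
    def test_published_masc_footnotes(self):
        sln = CEAInput("SLN", 5124, 72.98, MASC)
        slf = CEAInput("SLF", 6862, 66.79, MASC)
        llf = CEAInput("LLF", 10_248, 66.70, MASC)
        assert round(icer(sln, slf).value) == 281
        assert round(icer(slf, llf).value) == 37_622

    def test_published_smfq_footnote(self):
        sln = CEAInput("SLN", 5124, 11.84, SMFQ)
        lln = CEAInput("LLN", 8510, 9.75, SMFQ)
        assert round(icer(sln, lln).value) == 1620

    def test_equal_effects_is_undefined_not_exception(self):
        a = CEAInput("A", 100, 5.0, HRQOL)
        b = CEAInput("B", 200, 5.0, HRQOL)
        result = icer(a, b)
        assert not result.defined
        assert result.value == math.inf

    def test_identical_strategy_rejected(self):
        a = CEAInput("A", 100, 5.0, HRQOL)
        with pytest.raises(ValueError, match="itself"):
            icer(a, a)

    def test_cost_order_enforced(self):
        a = CEAInput("A", 300, 5.0, HRQOL)
        b = CEAInput("B", 200, 6.0, HRQOL)
        with pytest.raises(ValueError, match="at least as costly"):
            icer(a, b)


class TestGoldenFrontiers:
    def test_anxiety_frontier(self):
        rows, result = classify_and_build_frontier(make_inputs(ACC_MASC, MASC))
        assert result.frontier == ("SLN", "SLF", "LLF")
        assert [round(v) for v in result.frontier_icers] == [281, 37_622]
        off = {r.strategy for r in rows if r.classification is not Classification.FRONTIER}
        assert off == {"LLN", "SHN", "SHF", "LHN", "LHF"}

    def test_depression_frontier_with_extended_dominance(self):
        rows, result = classify_and_build_frontier(make_inputs(ACC_SMFQ, SMFQ))
        assert result.frontier == ("SLN", "LLN")
        assert [round(v) for v in result.frontier_icers] == [1620]
        by_code = {r.strategy: r.classification for r in rows}
        assert by_code["SLF"] is Classification.EXTENDED_DOMINATED
        assert by_code["SHN"] is Classification.EXTENDED_DOMINATED
        for code in ("SHF", "LLF", "LHN", "LHF"):
            assert by_code[code] is Classification.DOMINATED

    def test_qaly_frontier(self):
        rows, result = classify_and_build_frontier(make_inputs(ACC_QALY, HRQOL))
        assert result.frontier == ("SLN", "LLN")
        assert result.frontier_icers[0] == pytest.approx(96_743, abs=1.0)
        by_code = {r.strategy: r.classification for r in rows}
        assert by_code["SLF"] is Classification.EXTENDED_DOMINATED
        assert by_code["SHN"] is Classification.EXTENDED_DOMINATED

    def test_incremental_cost_column(self):
        rows, _ = classify_and_build_frontier(make_inputs(ACC_MASC, MASC))
        assert [r.incr_cost for r in rows] == [
            None, 1738, 1146, 502, 1236, 502, 1146, 1738,
        ]

    def test_negative_icer_reported_for_dominated_rows(self):
        rows, _ = classify_and_build_frontier(make_inputs(ACC_MASC, MASC))
        by_code = {r.strategy: r for r in rows}
        assert round(by_code["SHN"].icer.value) == -205
        assert by_code["SHN"].classification is Classification.DOMINATED

    def test_rows_frame_layout(self):
        rows, _ = classify_and_build_frontier(make_inputs(ACC_SMFQ, SMFQ))
        frame = rows_to_frame(rows)
        assert list(frame["strategy"]) == sorted(COSTS, key=COSTS.get)
        assert frame["cost"].is_monotonic_increasing
        assert frame.loc[frame["strategy"] == "LLN", "frontier_icer"].item() == (
            pytest.approx(1620.1, abs=0.1)
        )


class TestCetVerdict:
    def test_qaly_frontier_below_lowest_threshold(self):
        _, result = classify_and_build_frontier(make_inputs(ACC_QALY, HRQOL))
        assert result.cet_verdicts == ("below_range",)
        assert cet_verdict(result) == ("below_range",)

    def test_bound_checks(self):
        low, high = CET_RANGE_NOK
        _, result = classify_and_build_frontier(
            [
                CEAInput("A", 0, 0.1, HRQOL),
                CEAInput("B", 50_000, 0.2, HRQOL),  # ICER 500,000: within
                CEAInput("C", 140_000, 0.3, HRQOL),  # ICER 900,000: above
            ]
        )
        assert result.frontier_icers == pytest.approx((500_000, 900_000))
        assert result.cet_verdicts == ("within_range", "above_range")

    def test_no_threshold_for_symptom_scores(self):
        _, result = classify_and_build_frontier(make_inputs(ACC_MASC, MASC))
        assert result.cet_verdicts is None
        assert "no cost-effectiveness threshold" in result.note
        with pytest.raises(ValueError, match="threshold"):
            cet_verdict(result)


class TestEdgeCases:
    def test_single_strategy(self):
        rows, result = classify_and_build_frontier([CEAInput("A", 10, 1.0, HRQOL)])
        assert result.frontier == ("A",)
        assert result.frontier_icers == ()
        assert rows[0].classification is Classification.FRONTIER

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            classify_and_build_frontier([])

    def test_duplicate_codes_rejected(self):
        inputs = [CEAInput("A", 1, 1.0, HRQOL), CEAInput("A", 2, 2.0, HRQOL)]
        with pytest.raises(ValueError, match="duplicate"):
            classify_and_build_frontier(inputs)

    def test_mixed_measures_rejected(self):
        inputs = [CEAInput("A", 1, 1.0, HRQOL), CEAInput("B", 2, 2.0, MASC)]
        with pytest.raises(ValueError, match="mix"):
            classify_and_build_frontier(inputs)

    def test_exact_ties_collapse_to_one_representative(self):
        inputs = [
            CEAInput("A", 100, 0.5, HRQOL),
            CEAInput("B", 100, 0.5, HRQOL),
            CEAInput("C", 200, 0.9, HRQOL),
        ]
        _, result = classify_and_build_frontier(inputs)
        assert result.frontier == ("A", "C")

    def test_equal_cost_tie_break_better_effect_first(self):
        inputs = [
            CEAInput("worse", 100, 0.4, HRQOL),
            CEAInput("better", 100, 0.6, HRQOL),
        ]
        rows, result = classify_and_build_frontier(inputs)
        assert result.frontier == ("better",)
        assert rows[0].strategy == "better"


def _random_instances(n_instances: int, seed: int):
    rng = np.random.default_rng(seed)
    for _ in range(n_instances):
        n = int(rng.integers(2, 9))
        costs = rng.uniform(0, 20_000, n)
        effects = rng.uniform(-10, 10, n)
        yield [
            CEAInput(f"S{i}", float(costs[i]), float(effects[i]), HRQOL)
            for i in range(n)
        ]


@pytest.mark.parametrize("seed", [0, 1])
def test_frontier_matches_bruteforce_oracle(seed):
    """Random instances: the iterative classification equals the convex-hull
    oracle exactly."""
    for inputs in _random_instances(250, seed):
        _, result = classify_and_build_frontier(inputs)
        expected = oracle_frontier([(s.strategy, s.cost, s.effect) for s in inputs])
        assert set(result.frontier) == expected


cea_instances = st.lists(
    st.tuples(st.floats(0, 1e5), st.floats(-50, 50)),
    min_size=1,
    max_size=8,
).map(
    lambda pairs: [
        CEAInput(f"S{i}", c, e, HRQOL) for i, (c, e) in enumerate(pairs)
    ]
)


@given(inputs=cea_instances)
def test_frontier_icers_strictly_increase(inputs):
    _, result = classify_and_build_frontier(inputs)
    icers = result.frontier_icers
    assert all(a < b for a, b in zip(icers, icers[1:]))


@given(inputs=cea_instances)
def test_no_frontier_member_is_weakly_dominated(inputs):
    _, result = classify_and_build_frontier(inputs)
    by_code = {s.strategy: s for s in inputs}
    for code in result.frontier:
        member = by_code[code]
        for other in inputs:
            if other.strategy == code:
                continue
            assert not (
                other.cost <= member.cost
                and other.effect >= member.effect
                and (other.cost < member.cost or other.effect > member.effect)
            )


@given(inputs=cea_instances)
def test_frontier_stable_under_removal_of_nonmembers(inputs):
    rows, result = classify_and_build_frontier(inputs)
    non_members = [r.strategy for r in rows if r.classification is not Classification.FRONTIER]
    for dropped in non_members:
        reduced = [s for s in inputs if s.strategy != dropped]
        _, again = classify_and_build_frontier(reduced)
        assert again.frontier == result.frontier


@given(inputs=cea_instances)
def test_orientation_symmetry(inputs):
    """Negating accumulated values while flipping the benefit direction leaves
    the frontier and its ICERs unchanged."""
    flipped_measure = MeasureSpec(
        "HRQOL", -1e6, 1e6, BenefitDirection.DECREASE, integer_valued=False
    )
    flipped = [
        CEAInput(s.strategy, s.cost, -s.accumulated, flipped_measure) for s in inputs
    ]
    _, direct = classify_and_build_frontier(inputs)
    _, mirrored = classify_and_build_frontier(flipped)
    assert mirrored.frontier == direct.frontier
    assert mirrored.frontier_icers == pytest.approx(direct.frontier_icers)
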