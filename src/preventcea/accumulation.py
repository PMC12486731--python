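"""Accumulation of repeated outcomes over the observation window.

Outcomes were measured at inclusion (T1, week 0), week 12 (T2) and week 62
(T3). For each arm the per-timepoint available-case means are summarised into
an accumulated score by the trapezoid rule over the 62-week window, expressed
in score-years::

    accumulated = (m1 + m2)/2 * 12/52 + (m2 + m3)/2 * 50/52

For the quality-of-life utility this area under the curve is the QALY count
for the window. Accumulation operates on arm means, not individual
trajectories, because per-timepoint Ns differ under available-case analysis;
a per-child completers-only variant is provided for sensitivity checks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .measures import HRQOL, MASC, SMFQ, MeasureSpec
from .strategies import StrategyCode

#: Record-table columns holding one measure at the three timepoints.
TIMEPOINT_COLUMNS = ("t1", "t2", "t3")

RECORD_COLUMNS = ("child_id", "strategy", "wave", "sex", "age") + tuple(
    f"{m.column_prefix}_{t}" for m in (MASC, SMFQ, HRQOL) for t in TIMEPOINT_COLUMNS
)


@dataclass(frozen=True)
class Schedule:
    """Measurement weeks and the week/year conversion for the AUC."""

    weeks: tuple[float, float, float] = (0.0, 12.0, 62.0)
    weeks_per_year: float = 52.0

    def __post_init__(self) -> None:
        if list(self.weeks) != sorted(self.weeks) or len(set(self.weeks)) != len(self.weeks):
            raise ValueError("timepoint weeks must be strictly increasing")
        if self.weeks_per_year <= 0:
            raise ValueError("weeks_per_year must be positive")

    @property
    def window_years(self) -> float:
        return (self.weeks[-1] - self.weeks[0]) / self.weeks_per_year


DEFAULT_SCHEDULE = Schedule()


@dataclass(frozen=True)
class TimepointMeans:
    """Available-case mean/SD/N of one measure in one arm at T1/T2/T3."""

    strategy: StrategyCode
    measure: MeasureSpec
    mean: tuple[float, float, float]
    sd: tuple[float | None, float | None, float | None]
    n: tuple[int, int, int]

    def __post_init__(self) -> None:
        for t, (m, k) in enumerate(zip(self.mean, self.n), start=1):
            if k < 1:
                raise ValueError(
                    f"{self.strategy.code}/{self.measure.name}: N at T{t} must be >= 1"
                )
            if not (self.measure.scale_min <= m <= self.measure.scale_max):
                raise ValueError(
                    f"{self.strategy.code}/{self.measure.name}: mean {m} at T{t} "
                    f"outside scale [{self.measure.scale_min}, {self.measure.scale_max}]"
                )


@dataclass(frozen=True)
class AccumulatedOutcome:
    """Trapezoidal area under the mean trajectory, in score-years
    (QALYs for the quality-of-life utility)."""

    strategy: StrategyCode
    measure: MeasureSpec
    value: float
    schedule: Schedule = DEFAULT_SCHEDULE


def trapezoid_accumulate(
    m1: float, m2: float, m3: float, schedule: Schedule = DEFAULT_SCHEDULE
) -> float:
    """Accumulate three timepoint means into score-years over the window.

    With the default schedule this is
    ``(m1+m2)/2 * 12/52 + (m2+m3)/2 * 50/52``.
    """
    values = np.asarray([m1, m2, m3], dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(
            "all three timepoint means must be finite; compute available-case "
            "means before accumulating"
        )
    return float(np.trapezoid(values, x=np.asarray(schedule.weeks)) / schedule.weeks_per_year)


def accumulate(tm: TimepointMeans, schedule: Schedule = DEFAULT_SCHEDULE) -> AccumulatedOutcome:
    """Accumulate an arm's timepoint means into an :class:`AccumulatedOutcome`."""
    value = trapezoid_accumulate(*tm.mean, schedule=schedule)
    return AccumulatedOutcome(tm.strategy, tm.measure, value, schedule)


def _measure_columns(measure: MeasureSpec) -> list[str]:
    return [f"{measure.column_prefix}_{t}" for t in TIMEPOINT_COLUMNS]


def timepoint_summary(
    records: pd.DataFrame,
    measure: MeasureSpec,
    strategy: StrategyCode,
    sd_single: float | None = None,
) -> TimepointMeans:
    """Available-case mean, sample SD (ddof=1) and N per timepoint for one arm.

    Children missing at a timepoint are excluded from that timepoint only.
    ``sd_single`` is reported when N=1 (default ``None``, i.e. missing).
    Raises ``ValueError`` if a timepoint has no observed values.
    """
    arm = records[records["strategy"] == strategy.code]
    means, sds, ns = [], [], []
    for t, col in zip(TIMEPOINT_COLUMNS, _measure_columns(measure)):
        values = pd.to_numeric(arm[col], errors="coerce").dropna()
        if values.empty:
            raise ValueError(
                f"no observed {measure.name} values for {strategy.code} at {t.upper()}"
            )
        means.append(float(values.mean()))
        sds.append(float(values.std(ddof=1)) if len(values) > 1 else sd_single)
        ns.append(int(len(values)))
    return TimepointMeans(strategy, measure, tuple(means), tuple(sds), tuple(ns))


def summarize_records(
    records: pd.DataFrame,
    measures: tuple[MeasureSpec, ...] = (MASC, SMFQ, HRQOL),
    schedule: Schedule = DEFAULT_SCHEDULE,
) -> pd.DataFrame:
    """Per-arm, per-measure timepoint summary with the accumulated score.

    One row per (strategy, measure); the tidy equivalent of the published
    outcome table.
    """
    rows = []
    for code in pd.unique(records["strategy"]):
        strategy = StrategyCode.from_code(code)
        for measure in measures:
            tm = timepoint_summary(records, measure, strategy)
            acc = accumulate(tm, schedule)
            row: dict[str, object] = {"strategy": code, "measure": measure.name}
            for i, t in enumerate(TIMEPOINT_COLUMNS):
                row[f"n_{t}"] = tm.n[i]
                row[f"mean_{t}"] = tm.mean[i]
                row[f"sd_{t}"] = tm.sd[i]
            row["accumulated"] = acc.value
            rows.append(row)
    return pd.DataFrame(rows)


def accumulate_per_child(
    records: pd.DataFrame,
    measure: MeasureSpec,
    strategy: StrategyCode,
    schedule: Schedule = DEFAULT_SCHEDULE,
) -> float:
    """Completers-only sensitivity variant: mean of per-child trapezoid AUCs
    over children observed at all three timepoints."""
    arm = records[records["strategy"] == strategy.code]
    cols = _measure_columns(measure)
    complete = arm[cols].apply(pd.to_numeric, errors="coerce").dropna()
    if complete.empty:
        raise ValueError(
            f"no completers for {strategy.code}/{measure.name}"
        )
    aucs = [trapezoid_accumulate(*row, schedule=schedule) for row in complete.to_numpy()]
    return float(np.mean(aucs))


def t1_correlations(
    records: pd.DataFrame,
    measures: tuple[MeasureSpec, ...] = (MASC, SMFQ, HRQOL),
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations among the measures at baseline.

    Returns one row per measure pair with ``r``, two-sided ``p`` and the
    number of complete pairs ``n``.
    """
    rows = []
    for a, b in itertools.combinations(measures, 2):
        col_a, col_b = f"{a.column_prefix}_t1", f"{b.column_prefix}_t1"
        pair = records[[col_a, col_b]].apply(pd.to_numeric, errors="coerce").dropna()
        if len(pair) < min_pairs:
            raise ValueError(
                f"need at least {min_pairs} complete pairs for "
                f"{a.name}-{b.name} at T1, got {len(pair)}"
            )
        x, y = pair[col_a].to_numpy(), pair[col_b].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            r, p = math.nan, math.nan
        else:
            r, p = stats.pearsonr(x, y)
        rows.append(
            {"measure_a": a.name, "measure_b": b.name, "r": float(r), "p": float(p), "n": len(pair)}
        )
    return pd.DataFrame(rows)


def read_records(path) -> pd.DataFrame:
    """Read a trial-record CSV (one row per child; empty cell = missing)."""
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record file {path} is missing columns: {missing}")
    if df.empty:
        raise ValueError(f"record file {path} contains no rows")
    return df


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)
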