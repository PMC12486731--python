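"""End-to-end orchestration: costs -> accumulation -> CEA tables -> frontier.

Two record sources are supported:

* *published-means mode* -- the published per-arm timepoint means are fed straight
  into accumulation, reproducing the published CEA arithmetic exactly and
  deterministically;
* *simulation mode* -- individual records are generated (or loaded from CSV),
  summarised available-case, then accumulated.

Each CEA is run twice: once at full input precision and once on display-rounded
inputs (integer NOK costs; accumulated scores at their printed precision),
because published incremental columns and footnote ICERs are computed from the
rounded table entries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import accumulation, costs as costs_mod, frontier as frontier_mod, simulate
from .accumulation import DEFAULT_SCHEDULE, Schedule, TimepointMeans
from .frontier import CEAInput, FrontierResult
from .measures import HRQOL, MASC, SMFQ, MeasureSpec
from .simulate import SimulationConfig, default_simulation_config
from .strategies import StrategyCode

ANALYSIS_MEASURES: tuple[MeasureSpec, ...] = (MASC, SMFQ, HRQOL)

#: Printed precision of accumulated scores in the published tables.
DISPLAY_DECIMALS = {"MASC": 2, "SMFQ": 2, "HRQOL": 3}


def published_means_summaries(
    config: SimulationConfig | None = None,
) -> list[TimepointMeans]:
    """Arm x measure timepoint summaries taken directly from the published
    summary grid (no individual records involved)."""
    config = config or default_simulation_config()
    out = []
    for code, arm in config.arms.items():
        strategy = StrategyCode.from_code(code)
        for measure in ANALYSIS_MEASURES:
            t = arm[measure.name]
            out.append(TimepointMeans(strategy, measure, t.mean, t.sd, t.n))
    return out


def accumulated_table(
    summaries: list[TimepointMeans], schedule: Schedule = DEFAULT_SCHEDULE
) -> pd.DataFrame:
    """One row per (strategy, measure) with timepoint means and the
    accumulated score."""
    rows = []
    for tm in summaries:
        acc = accumulation.accumulate(tm, schedule)
        rows.append(
            {
                "strategy": tm.strategy.code,
                "measure": tm.measure.name,
                "mean_t1": tm.mean[0],
                "mean_t2": tm.mean[1],
                "mean_t3": tm.mean[2],
                "accumulated": acc.value,
            }
        )
    return pd.DataFrame(rows)


def cea_inputs(
    accumulated: pd.DataFrame, cost_table: pd.DataFrame, measure: MeasureSpec
) -> list[CEAInput]:
    """Join per-child costs with accumulated outcomes for one measure."""
    cost_by_code = dict(zip(cost_table["strategy"], cost_table["cost_per_child"]))
    sub = accumulated[accumulated["measure"] == measure.name]
    missing = set(sub["strategy"]) - set(cost_by_code)
    if missing:
        raise ValueError(f"no cost available for strategies: {sorted(missing)}")
    return [
        CEAInput(r.strategy, cost_by_code[r.strategy], r.accumulated, measure)
        for r in sub.itertuples()
    ]


def round_inputs(inputs: list[CEAInput], effect_decimals: int) -> list[CEAInput]:
    """Display-rounded copies: integer NOK costs, accumulated at printed
    precision (the published tables difference these rounded values)."""
    return [
        CEAInput(
            s.strategy,
            round(s.cost),
            round(s.accumulated, effect_decimals),
            s.measure,
        )
        for s in inputs
    ]


@dataclass
class MeasureCEA:
    """Full-precision and rounded-input CEA for one measure."""

    measure: MeasureSpec
    table: pd.DataFrame  # merged display table
    result: FrontierResult  # full-precision classification
    rounded_result: FrontierResult

    @property
    def frontier(self) -> tuple[str, ...]:
        return self.result.frontier


def run_measure_cea(
    accumulated: pd.DataFrame,
    cost_table: pd.DataFrame,
    measure: MeasureSpec,
) -> MeasureCEA:
    inputs = cea_inputs(accumulated, cost_table, measure)
    rows, result = frontier_mod.classify_and_build_frontier(inputs)
    table = frontier_mod.rows_to_frame(rows)

    rounded = round_inputs(inputs, DISPLAY_DECIMALS.get(measure.name, 2))
    r_rows, r_result = frontier_mod.classify_and_build_frontier(rounded)
    r_table = frontier_mod.rows_to_frame(r_rows).add_suffix("_rounded")
    r_table = r_table.rename(columns={"strategy_rounded": "strategy"})
    table = table.merge(r_table, on="strategy", how="left")
    return MeasureCEA(measure=measure, table=table, result=result, rounded_result=r_result)


def run_cea(
    accumulated: pd.DataFrame,
    cost_table: pd.DataFrame,
    measures: tuple[MeasureSpec, ...] = ANALYSIS_MEASURES,
) -> dict[str, MeasureCEA]:
    return {m.name: run_measure_cea(accumulated, cost_table, m) for m in measures}


def frontier_to_dict(result: FrontierResult, rounded: FrontierResult) -> dict:
    return {
        "measure": result.measure.name,
        "frontier": list(result.frontier),
        "frontier_icers": list(result.frontier_icers),
        "frontier_icers_rounded_inputs": list(rounded.frontier_icers),
        "cet_range_nok": list(result.cet_range),
        "cet_verdicts": list(result.cet_verdicts) if result.cet_verdicts else None,
        "note": result.note,
    }


@dataclass
class PipelineArtifacts:
    cost_table: pd.DataFrame
    records: pd.DataFrame | None
    summary: pd.DataFrame | None
    accumulated: pd.DataFrame
    cea: dict[str, MeasureCEA]
    calibration: simulate.CalibrationReport | None


def run_all(
    seed: int | None = None,
    records: pd.DataFrame | None = None,
    published_means: bool = False,
    sim_config: SimulationConfig | None = None,
    unit_costs: costs_mod.UnitCosts | None = None,
    base_profile: costs_mod.ResourceProfile | None = None,
    schedule: Schedule = DEFAULT_SCHEDULE,
) -> PipelineArtifacts:
    """Run the whole analysis from one of the three record sources.

    Exactly one of ``published_means``, ``records`` or ``seed`` selects the
    source: published means, a provided record table, or a fresh synthetic
    trial.
    """
    sources = sum([published_means, records is not None, seed is not None])
    if sources != 1:
        raise ValueError(
            "specify exactly one record source: published_means=True, records=..., "
            "or seed=... for simulation"
        )
    sim_config = sim_config or default_simulation_config()
    cost_df = costs_mod.cost_table(
        unit_costs or costs_mod.DEFAULT_UNIT_COSTS, base_profile
    )

    calibration = None
    summary = None
    if published_means:
        summaries = published_means_summaries(sim_config)
        acc = accumulated_table(summaries, schedule)
    else:
        if records is None:
            records = simulate.generate_trial(sim_config, seed)
            calibration = simulate.validate_against_targets(records, sim_config)
        summary = accumulation.summarize_records(records, ANALYSIS_MEASURES, schedule)
        acc = summary.rename(columns={"accumulated": "accumulated"})[
            ["strategy", "measure", "mean_t1", "mean_t2", "mean_t3", "accumulated"]
        ]
    cea = run_cea(acc, cost_df)
    return PipelineArtifacts(
        cost_table=cost_df,
        records=records,
        summary=summary,
        accumulated=acc,
        cea=cea,
        calibration=calibration,
    )


def write_artifacts(artifacts: PipelineArtifacts, out_dir: str | Path) -> list[Path]:
    """Write every artifact as CSV/JSON under ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_csv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)

    save_csv(artifacts.cost_table, "costs.csv")
    if artifacts.records is not None:
        save_csv(artifacts.records, "records.csv")
    if artifacts.summary is not None:
        save_csv(artifacts.summary, "summary.csv")
    save_csv(artifacts.accumulated, "accumulated.csv")
    for name, cea in artifacts.cea.items():
        save_csv(cea.table, f"cea_{name.lower()}.csv")
        plot_df = cea.table[["strategy", "cost", "accumulated", "classification"]]
        save_csv(plot_df, f"frontier_plot_{name.lower()}.csv")
        path = out / f"frontier_{name.lower()}.json"
        path.write_text(
            json.dumps(frontier_to_dict(cea.result, cea.rounded_result), indent=2)
        )
        written.append(path)
    if artifacts.calibration is not None:
        path = out / "calibration.json"
        path.write_text(artifacts.calibration.to_json())
        written.append(path)
        path = out / "calibration.txt"
        path.write_text(artifacts.calibration.to_text() + "\n")
        written.append(path)
    return written


def plot_frontier(cea: MeasureCEA, path: str | Path) -> None:
    """Optional rendering of the frontier scatter (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = cea.table
    fig, ax = plt.subplots(figsize=(6, 4))
    on = df["classification"] == "frontier"
    ax.plot(
        df.loc[on, "accumulated"], df.loc[on, "cost"], "o-", color="tab:blue",
        label="frontier",
    )
    ax.plot(
        df.loc[~on, "accumulated"], df.loc[~on, "cost"], "x", color="tab:red",
        label="dominated / extended dominated",
    )
    for r in df.itertuples():
        ax.annotate(r.strategy, (r.accumulated, r.cost), fontsize=8,
                    xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel(f"accumulated {cea.measure.name}")
    ax.set_ylabel("cost per child (NOK)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
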