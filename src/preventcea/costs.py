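"""Micro-costing of group delivery from a health-service perspective.

Per-group cost of a strategy is assembled bottom-up from group-leader time and
flat per-group items::

    per_group = hours_per_leader * loaded_rate * group_leaders   (labor)
              + workbooks                                        (materials)
              + app fee (feedback strategies only)
              + flat supervision fee

where ``hours_per_leader`` counts child and parent sessions with one hour of
preparation each, weekly feedback-system review (8 h total for feedback
strategies), 4 h of supervision and 2 h of recruitment/screening. Cost per
child divides by the average group size (5). All amounts are NOK; no
discounting is applied over the 62-week horizon.

Only delivery costs are included: societal costs (parental absence, other
service use) are deliberately out of scope for this perspective.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .strategies import (
    ALL_STRATEGIES,
    Delivery,
    Feedback,
    ParentalInvolvement,
    StrategyCode,
)


class ConfigurationError(ValueError):
    """A resource profile, unit-cost set, or config file is inconsistent."""


@dataclass(frozen=True)
class ResourceProfile:
    """Resource quantities for delivering one strategy to one group."""

    child_sessions: int
    parent_sessions: int
    child_session_duration: float = 1.0  # hours
    parent_session_duration: float = 1.5  # hours
    prep_per_session: float = 1.0  # hours, child and parent sessions alike
    mfs_review_hours: float = 0.0  # total over the course; 8.0 under feedback
    supervision_hours_per_leader: float = 4.0
    recruitment_hours_per_leader: float = 2.0
    group_leaders: int = 2
    group_size: int = 5

    def __post_init__(self) -> None:
        for field in (
            "child_sessions",
            "parent_sessions",
            "child_session_duration",
            "parent_session_duration",
            "prep_per_session",
            "mfs_review_hours",
            "supervision_hours_per_leader",
            "recruitment_hours_per_leader",
        ):
            if getattr(self, field) < 0:
                raise ConfigurationError(f"{field} must be non-negative")
        if self.group_leaders < 1:
            raise ConfigurationError("group_leaders must be >= 1")
        if self.group_size < 1:
            raise ConfigurationError("group_size must be >= 1")


@dataclass(frozen=True)
class UnitCosts:
    """Unit costs in NOK. The loaded hourly rate may be given directly or
    derived as base wage x social-cost multiplier."""

    loaded_hourly_rate: float | None = None
    base_hourly_wage: float | None = None
    social_cost_multiplier: float = 1.4
    workbooks_low_parental: float = 1345.0  # per group
    workbooks_high_parental: float = 2540.0  # per group
    workbooks_per_child: float = 0.0  # optional extra for new scenarios
    mfs_app: float = 225.0  # per group, feedback strategies only
    supervision_fee: float = 1000.0  # flat per group

    def __post_init__(self) -> None:
        if self.loaded_hourly_rate is None and self.base_hourly_wage is None:
            raise ConfigurationError(
                "either loaded_hourly_rate or base_hourly_wage must be supplied"
            )
        for field in (
            "loaded_hourly_rate",
            "base_hourly_wage",
            "social_cost_multiplier",
            "workbooks_low_parental",
            "workbooks_high_parental",
            "workbooks_per_child",
            "mfs_app",
            "supervision_fee",
        ):
            value = getattr(self, field)
            if value is not None and value < 0:
                raise ConfigurationError(f"{field} must be non-negative")

    @property
    def hourly_rate(self) -> float:
        """Loaded (social-cost-inclusive) group-leader rate, NOK/hour."""
        if self.loaded_hourly_rate is not None:
            return self.loaded_hourly_rate
        return self.base_hourly_wage * self.social_cost_multiplier


#: The published costing: loaded rate 529 NOK/h, standard per-group fees.
DEFAULT_UNIT_COSTS = UnitCosts(loaded_hourly_rate=529.0)


@dataclass(frozen=True)
class CostBreakdown:
    """Per-group and per-child cost decomposition for one strategy."""

    strategy: StrategyCode
    hours_per_leader: float
    labor: float
    materials: float
    app: float
    supervision: float
    group_size: int

    @property
    def per_group(self) -> float:
        return self.labor + self.materials + self.app + self.supervision

    @property
    def per_child(self) -> float:
        return self.per_group / self.group_size


def session_prep_hours(profile: ResourceProfile) -> float:
    """Total session plus preparation hours for one leader over the course."""
    return profile.child_sessions * (
        profile.child_session_duration + profile.prep_per_session
    ) + profile.parent_sessions * (
        profile.parent_session_duration + profile.prep_per_session
    )


def hours_per_group_leader(profile: ResourceProfile) -> float:
    """All paid hours of one group leader: sessions + prep, feedback review,
    supervision and recruitment/screening."""
    return (
        session_prep_hours(profile)
        + profile.mfs_review_hours
        + profile.supervision_hours_per_leader
        + profile.recruitment_hours_per_leader
    )


def profile_for(strategy: StrategyCode, base: ResourceProfile | None = None) -> ResourceProfile:
    """The faithful resource profile for a strategy.

    ``base`` carries durations/overheads; session counts and feedback review
    hours are set from the strategy's factors (hybrid 8 / long 16 child
    sessions; 0/5 parent sessions; 8 h review iff feedback).
    """
    if base is None:
        base = ResourceProfile(child_sessions=0, parent_sessions=0)
    return replace(
        base,
        child_sessions=16 if strategy.delivery is Delivery.LONG else 8,
        parent_sessions=5 if strategy.parental is ParentalInvolvement.HIGH else 0,
        mfs_review_hours=8.0 if strategy.feedback is Feedback.MFS else 0.0,
    )


def _check_consistency(profile: ResourceProfile, strategy: StrategyCode) -> None:
    if strategy.feedback is Feedback.MFS and profile.mfs_review_hours == 0:
        raise ConfigurationError(
            f"{strategy.code}: feedback strategy but mfs_review_hours is 0"
        )
    if strategy.feedback is Feedback.NONE and profile.mfs_review_hours != 0:
        raise ConfigurationError(
            f"{strategy.code}: no-feedback strategy but mfs_review_hours is "
            f"{profile.mfs_review_hours}"
        )
    if strategy.parental is ParentalInvolvement.HIGH and profile.parent_sessions == 0:
        raise ConfigurationError(
            f"{strategy.code}: high parental involvement but parent_sessions is 0"
        )
    if strategy.parental is ParentalInvolvement.LOW and profile.parent_sessions != 0:
        raise ConfigurationError(
            f"{strategy.code}: low parental involvement but parent_sessions is "
            f"{profile.parent_sessions}"
        )


def group_cost(
    profile: ResourceProfile,
    costs: UnitCosts,
    strategy: StrategyCode,
) -> CostBreakdown:
    """Cost one intervention group under a strategy.

    Raises :class:`ConfigurationError` if the profile contradicts the
    strategy's factors (e.g. feedback review hours for a no-feedback arm).
    """
    _check_consistency(profile, strategy)
    hours = hours_per_group_leader(profile)
    labor = hours * costs.hourly_rate * profile.group_leaders
    materials = (
        costs.workbooks_high_parental
        if strategy.parental is ParentalInvolvement.HIGH
        else costs.workbooks_low_parental
    ) + costs.workbooks_per_child * profile.group_size
    app = costs.mfs_app if strategy.feedback is Feedback.MFS else 0.0
    return CostBreakdown(
        strategy=strategy,
        hours_per_leader=hours,
        labor=labor,
        materials=materials,
        app=app,
        supervision=costs.supervision_fee,
        group_size=profile.group_size,
    )


def child_cost(breakdown: CostBreakdown, group_size: int | None = None) -> float:
    """Cost per child: per-group cost divided by group size."""
    size = breakdown.group_size if group_size is None else group_size
    if size == 0:
        raise ZeroDivisionError("group_size must be >= 1 to compute cost per child")
    if size < 0:
        raise ConfigurationError("group_size must be >= 1")
    return breakdown.per_group / size


def cost_table(
    unit_costs: UnitCosts = DEFAULT_UNIT_COSTS,
    base_profile: ResourceProfile | None = None,
    strategies: tuple[StrategyCode, ...] = ALL_STRATEGIES,
) -> pd.DataFrame:
    """Cost all strategies; one row each, sorted by cost per child ascending.

    Columns mirror the published resource/cost table plus the factor triple.
    """
    rows = []
    for strategy in strategies:
        profile = profile_for(strategy, base_profile)
        bd = group_cost(profile, unit_costs, strategy)
        rows.append(
            {
                "strategy": strategy.code,
                "delivery": strategy.delivery.name.lower(),
                "parental": strategy.parental.name.lower(),
                "feedback": strategy.feedback.name.lower(),
                "child_sessions": profile.child_sessions,
                "parent_sessions": profile.parent_sessions,
                "session_prep_hours": session_prep_hours(profile),
                "mfs_review_hours": profile.mfs_review_hours,
                "supervision_hours": profile.supervision_hours_per_leader,
                "recruitment_hours": profile.recruitment_hours_per_leader,
                "hours_per_leader": bd.hours_per_leader,
                "hourly_rate": unit_costs.hourly_rate,
                "labor": bd.labor,
                "materials": bd.materials,
                "app": bd.app,
                "supervision_fee": bd.supervision,
                "cost_per_group": bd.per_group,
                "cost_per_child": bd.per_child,
            }
        )
    df = pd.DataFrame(rows).sort_values("cost_per_child", kind="stable")
    return df.reset_index(drop=True)


def load_cost_config(path: str | Path | None = None) -> tuple[ResourceProfile, UnitCosts]:
    """Load a cost configuration file (YAML).

    Returns a base resource profile (session counts filled per strategy by
    :func:`profile_for`) and the unit costs. Without ``path`` the packaged
    default configuration is used.
    """
    if path is None:
        text = (
            resources.files("preventcea").joinpath("data/default_costs.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "unit_costs" not in raw:
        raise ConfigurationError("cost config must contain a 'unit_costs' mapping")
    uc = dict(raw["unit_costs"])
    unit_costs = UnitCosts(
        loaded_hourly_rate=uc.get("loaded_hourly_rate"),
        base_hourly_wage=uc.get("base_hourly_wage"),
        social_cost_multiplier=uc.get("social_cost_multiplier", 1.4),
        workbooks_low_parental=uc.get("workbooks_low_parental", 1345.0),
        workbooks_high_parental=uc.get("workbooks_high_parental", 2540.0),
        workbooks_per_child=uc.get("workbooks_per_child", 0.0),
        mfs_app=uc.get("mfs_app", 225.0),
        supervision_fee=uc.get("supervision_fee", 1000.0),
    )
    res = dict(raw.get("resources", {}))
    base = ResourceProfile(
        child_sessions=0,
        parent_sessions=0,
        child_session_duration=res.get("child_session_duration", 1.0),
        parent_session_duration=res.get("parent_session_duration", 1.5),
        prep_per_session=res.get("prep_per_session", 1.0),
        mfs_review_hours=0.0,
        supervision_hours_per_leader=res.get("supervision_hours_per_leader", 4.0),
        recruitment_hours_per_leader=res.get("recruitment_hours_per_leader", 2.0),
        group_leaders=res.get("group_leaders", 2),
        group_size=res.get("group_size", 5),
    )
    return base, unit_costs
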