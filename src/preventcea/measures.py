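"""Outcome measure definitions.

Three health outcomes are analysed: anxiety symptoms (MASC, 0-117, lower is
better), depressive symptoms (SMFQ, 0-26, lower is better), and a
health-related quality-of-life utility on [0, 1] (higher is better), whose
accumulated value over time is a QALY count. Utilities are consumed directly;
mapping a quality-of-life questionnaire onto a utility is out of scope and
handled upstream (a pass-through by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class BenefitDirection(Enum):
    """Which direction of a score is a health improvement."""

    DECREASE = "decrease"
    INCREASE = "increase"


@dataclass(frozen=True)
class MeasureSpec:
    """Scale and orientation of one outcome measure."""

    name: str
    scale_min: float
    scale_max: float
    benefit_direction: BenefitDirection
    integer_valued: bool = False

    def __post_init__(self) -> None:
        if not self.scale_min < self.scale_max:
            raise ValueError(
                f"{self.name}: scale_min must be < scale_max "
                f"(got {self.scale_min}, {self.scale_max})"
            )

    @property
    def improves_by_decrease(self) -> bool:
        return self.benefit_direction is BenefitDirection.DECREASE

    @property
    def column_prefix(self) -> str:
        """Column-name prefix used in trial record tables (e.g. ``masc_t1``)."""
        return self.name.lower()


MASC = MeasureSpec("MASC", 0, 117, BenefitDirection.DECREASE, integer_valued=True)
SMFQ = MeasureSpec("SMFQ", 0, 26, BenefitDirection.DECREASE, integer_valued=True)
HRQOL = MeasureSpec("HRQOL", 0.0, 1.0, BenefitDirection.INCREASE, integer_valued=False)

MEASURES: dict[str, MeasureSpec] = {m.name: m for m in (MASC, SMFQ, HRQOL)}


def get_measure(name: str) -> MeasureSpec:
    try:
        return MEASURES[name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown measure {name!r}; expected one of {sorted(MEASURES)}"
        ) from None
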