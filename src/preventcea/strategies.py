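"""The eight delivery strategies as a 2x2x2 factor structure.

The intervention was optimised over three binary factors:

* delivery format -- 16 in-person child sessions (``L``, long) versus a hybrid
  of 8 in-person plus 8 web-based sessions (``S``, short/hybrid);
* parental involvement -- five parent group sessions (``H``, high) versus a
  self-help brochure (``L``, low);
* measurement feedback -- a measurement feedback system reviewed weekly by the
  group leaders (``F``) versus none (``N``).

Every strategy is a three-letter code, first letter S/L, second L/H, third N/F;
e.g. ``SLN`` is hybrid delivery, brochure-only parental involvement, no
feedback, and ``LHF`` is the most resource-intensive combination.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Delivery(Enum):
    HYBRID = "S"  # 8 in-person + 8 web-based child sessions
    LONG = "L"  # 16 in-person child sessions


class ParentalInvolvement(Enum):
    LOW = "L"  # self-help brochure
    HIGH = "H"  # five parent group sessions


class Feedback(Enum):
    NONE = "N"
    MFS = "F"  # measurement feedback system


@dataclass(frozen=True)
class StrategyCode:
    """One of the eight factor combinations."""

    delivery: Delivery
    parental: ParentalInvolvement
    feedback: Feedback

    @property
    def code(self) -> str:
        return self.delivery.value + self.parental.value + self.feedback.value

    @classmethod
    def from_code(cls, code: str) -> "StrategyCode":
        token = code.strip().upper()
        if len(token) != 3:
            raise ValueError(f"strategy code must have 3 letters, got {code!r}")
        try:
            return cls(Delivery(token[0]), ParentalInvolvement(token[1]), Feedback(token[2]))
        except ValueError:
            raise ValueError(
                f"invalid strategy code {code!r}: letters must be S/L, L/H, N/F"
            ) from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


def all_strategies() -> tuple[StrategyCode, ...]:
    """All eight factor combinations, ordered from least to most resource
    intensive (the published table ordering)."""
    return tuple(
        StrategyCode.from_code(c)
        for c in ("SLN", "SLF", "SHN", "LLN", "SHF", "LLF", "LHN", "LHF")
    )


ALL_STRATEGIES = all_strategies()
STRATEGY_CODES = tuple(s.code for s in ALL_STRATEGIES)
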