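"""Reporting conventions: decimal truncation/rounding and duration rendering.

The field-study tables that this package reproduces print values that are
*truncated*, not rounded, to two decimals (e.g. 12.5/11.5 = 1.0869... is
printed as 1.08, and 35.198... as 35.19).  ``ReportingPolicy`` makes that
convention explicit and configurable.  Durations appear in two styles:
decimal minutes ("38.74 min") for analytic indicators and minute+second
("24 min + 24 sec") for simulation tables; both are handled here.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

from .errors import InvalidParameterError

__all__ = [
    "ReportingPolicy",
    "STUDY_POLICY",
    "truncate",
    "format_min_sec",
    "parse_duration",
]


def truncate(x: float, decimals: int = 2) -> float:
    """Truncate ``x`` toward zero at ``decimals`` decimal places.

    A pre-round at 9 decimals absorbs binary floating-point noise so that a
    value that is mathematically exactly on a decimal boundary (e.g. 32.592)
    is not pushed below it.
    """
    q = Decimal(repr(round(float(x), 9))).quantize(
        Decimal(1).scaleb(-decimals), rounding=ROUND_DOWN
    )
    return float(q)


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(repr(round(float(x), 9))).quantize(
        Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass(frozen=True)
class ReportingPolicy:
    """How computed indicators are reduced to printed numbers.

    mode
        ``"truncate"`` drops digits beyond ``decimals`` (the study tables'
        evident convention); ``"round"`` is conventional half-up rounding.
    decimals
        Number of decimal places kept (0..6).
    """

    mode: str = "truncate"
    decimals: int = 2

    def __post_init__(self) -> None:
        if self.mode not in ("truncate", "round"):
            raise InvalidParameterError(f"unknown reporting mode {self.mode!r}")
        if not (0 <= int(self.decimals) <= 6):
            raise InvalidParameterError("decimals must be in 0..6")

    def apply(self, x: float, decimals: int | None = None) -> float:
        """Format a single value; ``decimals`` overrides the policy default."""
        d = self.decimals if decimals is None else int(decimals)
        if self.mode == "truncate":
            return truncate(x, d)
        return _round_half_up(x, d)


#: Policy that reproduces the field study's printed tables bit-exactly.
STUDY_POLICY = ReportingPolicy(mode="truncate", decimals=2)


def format_min_sec(minutes: float) -> str:
    """Render a duration in the simulation tables' "M min + S sec" style.

    Sub-minute durations render as "S sec"; seconds are rounded to the
    nearest integer, with carry (59.7 s -> "1 min + 0 sec").
    """
    if minutes < 0 or not math.isfinite(minutes):
        raise InvalidParameterError("duration must be finite and non-negative")
    total_sec = int(round(minutes * 60.0))
    m, s = divmod(total_sec, 60)
    if m == 0:
        return f"{s} sec"
    return f"{m} min + {s} sec"


_DURATION_RE = re.compile(
    r"^\s*(?:(\d+)\s*min(?:ute)?s?)?"
    r"\s*(?:and|\+)?\s*"
    r"(?:(\d+)\s*sec(?:ond)?s?)?\s*$",
    re.IGNORECASE,
)


def parse_duration(text: str) -> float:
    """Parse "24 minutes and 24 seconds", "1 min + 26 sec" or "46 sec"
    into decimal minutes."""
    m = _DURATION_RE.match(text)
    if m is None or (m.group(1) is None and m.group(2) is None):
        raise InvalidParameterError(f"cannot parse duration {text!r}")
    minutes = int(m.group(1) or 0)
    seconds = int(m.group(2) or 0)
    return minutes + seconds / 60.0
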