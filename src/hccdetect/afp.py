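"""Censored serum AFP values.

Clinical AFP assays report a point concentration in ng/mL, but values below
the assay's limit of detection come back as "<bound" and values above its
saturation point as ">=10,000".  A censored value must never be silently
replaced by a fabricated point value, so the bound and the censoring flag
travel together through the pipeline.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Union

__all__ = ["CensoredAfp", "parse_afp", "DEFAULT_LOWER_BOUND", "DEFAULT_UPPER_BOUND"]

DEFAULT_LOWER_BOUND = 0.8
DEFAULT_UPPER_BOUND = 10_000.0

_CENSOR_KINDS = ("none", "lt", "ge")

_PARSE_RE = re.compile(r"^\s*(<|>=|≥)?\s*([0-9.,]+)\s*$")


@dataclass(frozen=True)
class CensoredAfp:
    """An AFP measurement in ng/mL, possibly censored.

    ``value`` is the point value when ``censor == "none"``, otherwise the
    censoring bound (the detection limit for ``"lt"``, the saturation bound
    for ``"ge"``).
    """

    value: float
    censor: str = "none"

    def __post_init__(self) -> None:
        if self.censor not in _CENSOR_KINDS:
            raise ValueError(f"censor must be one of {_CENSOR_KINDS}, got {self.censor!r}")
        if not math.isfinite(self.value) or self.value < 0:
            raise ValueError(f"AFP value must be finite and nonnegative, got {self.value}")

    @property
    def is_censored(self) -> bool:
        return self.censor != "none"

    def point_estimate(self) -> float:
        """Point substitute used where a single number is unavoidable.

        Below-detection values map to half the bound, saturated values to the
        bound itself; both are monotone and bounded substitutes.
        """
        if self.censor == "lt":
            return self.value / 2.0
        return self.value

    def ln(self) -> float:
        """Natural log of the point substitute (the classifier attribute)."""
        p = self.point_estimate()
        if p <= 0:
            raise ValueError("cannot take log of a nonpositive AFP substitute")
        return math.log(p)

    def geq(self, cutoff: float) -> bool:
        """Decision-rule comparison: is the AFP at or above ``cutoff``?

        Comparison is on the reported point value, or on the censoring bound:
        ">=10,000" is at or above any cutoff up to its bound; "<0.8" is below
        any cutoff at or above its bound.
        """
        if self.censor == "lt":
            # true value < bound; can only be >= cutoff if cutoff < bound,
            # which is unknowable -- treat conservatively as below.
            return False
        return self.value >= cutoff

    def __str__(self) -> str:
        if self.censor == "lt":
            return f"<{self.value:g}"
        if self.censor == "ge":
            return f">={self.value:g}"
        return f"{self.value:g}"


def parse_afp(text: Union[str, float, CensoredAfp]) -> CensoredAfp:
    """Parse an AFP report such as ``"4.7"``, ``"<0.8"`` or ``">=10000"``."""
    if isinstance(text, CensoredAfp):
        return text
    if isinstance(text, (int, float)):
        return CensoredAfp(float(text))
    m = _PARSE_RE.match(str(text).replace(",", ""))
    if not m:
        raise ValueError(f"unparseable AFP value: {text!r}")
    sym, num = m.groups()
    value = float(num)
    if sym == "<":
        return CensoredAfp(value, "lt")
    if sym in (">=", "≥"):
        return CensoredAfp(value, "ge")
    return CensoredAfp(value)
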