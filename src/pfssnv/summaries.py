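"""Small dataset-comparison arithmetic used in summary tables."""

from __future__ import annotations

import math

from .io_model import PfsSnvError


def percent_increase(previous: float, current: float, ndigits: int = 1) -> float:
    """100 * (current - previous) / previous, rounded to ``ndigits``."""
    if previous <= 0:
        raise PfsSnvError("previous total must be positive")
    return round(100.0 * (current - previous) / previous, ndigits)


def round_sig(value: float, digits: int = 1) -> float:
    """Round to the given number of significant digits."""
    if value == 0:
        return 0.0
    if digits < 1:
        raise PfsSnvError("digits must be >= 1")
    exponent = math.floor(math.log10(abs(value)))
    return round(value, -exponent + digits - 1)
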