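"""Display rounding for reports.

All engine computation keeps full floating precision; every number that
appears in a report is rounded here, with round-half-away-from-zero
(the convention used in published classification-accuracy tables,
unlike Python's banker's rounding).
"""

from __future__ import annotations

import math

__all__ = ["round_half_away", "as_percent", "fmt_rate", "fmt_metric"]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with halves going away from zero (0.5 -> 1, -0.5 -> -1)."""
    if not math.isfinite(x):
        return x
    factor = 10.0**ndigits
    scaled = x * factor
    floor = math.floor(abs(scaled))
    frac = abs(scaled) - floor
    # nudge for float representation of exact halves (e.g. 2.675*100)
    if frac >= 0.5 - 1e-9:
        floor += 1
    return math.copysign(floor, scaled) / factor


def as_percent(proportion: float, ndigits: int = 1) -> float:
    """Proportion -> percent at the stated display precision."""
    return round_half_away(100.0 * proportion, ndigits)


def fmt_rate(proportion: float) -> str:
    """Base rates as one-decimal percents, e.g. ``'12.2'``."""
    return f"{as_percent(proportion, 1):.1f}"


def fmt_metric(value: float, ndigits: int = 2) -> str:
    """Sens/spec/AUC-style metrics at 2-3 decimals, leading zero kept."""
    return f"{round_half_away(value, ndigits):.{ndigits}f}"
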