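"""Small shared numeric helpers."""

from __future__ import annotations

import math


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with halves away from zero (the convention of the printed summary tables).

    Python's built-in ``round`` uses banker's rounding, which would turn e.g.
    a mean of 35.75 into 35.7 instead of the conventional 35.8.
    """
    if math.isnan(x):
        return x
    factor = 10.0 ** ndigits
    scaled = abs(x) * factor
    rounded = math.floor(scaled + 0.5)
    result = math.copysign(rounded / factor, x)
    return result if ndigits > 0 else float(int(result))


def pct(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """Percentage with half-away-from-zero rounding; nan for a zero denominator."""
    if denominator == 0:
        return math.nan
    return round_half_away(100.0 * numerator / denominator, ndigits)
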