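"""Half-away-from-zero rounding used for all reported percentages."""

from __future__ import annotations

import math


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero.

    Python's built-in ``round`` uses banker's rounding; reported percentages
    here follow the conventional half-away-from-zero rule instead.
    """
    if not math.isfinite(x):
        return x
    factor = 10.0**ndigits
    scaled = x * factor
    rounded = math.floor(abs(scaled) + 0.5)
    result = math.copysign(rounded, scaled) / factor
    return result if ndigits > 0 else float(result)
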