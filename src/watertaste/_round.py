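"""Half-away-from-zero decimal rounding, used only at the reporting layer.

Computations keep full floating-point precision throughout; values are
rounded to the printed number of decimals (2 dp for estimates, 1 dp for
percentages) only when displayed or serialized, with ties rounded away
from zero in the conventional "school" style rather than Python's
banker's rounding.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))
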