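"""One-decimal reporting arithmetic with round-half-away-from-zero.

Python's built-in ``round`` is banker's rounding (14/17 -> 82.35 -> 82.3 %);
published family surveys print half-up values (82.4 %), so all reported
ratios go through :func:`round_half_away`.
"""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)
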