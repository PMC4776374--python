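"""Reported-ratio arithmetic shared by all summary tables.

Every percentage or fold ratio the pipeline prints is one of these two
operations, so summaries are always recomputable from the integer counts
they summarise.
"""
from __future__ import annotations

from .rounding import round_half_away


def percentage(k: int, n: int) -> float:
    """100*k/n rounded to one decimal, half away from zero."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    return round_half_away(100.0 * k / n, 1)


def fold_ratio(a: int, b: int) -> float:
    """a/b rounded to one decimal, half away from zero."""
    if b <= 0:
        raise ValueError("denominator must be positive")
    return round_half_away(a / b, 1)
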