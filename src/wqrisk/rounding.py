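"""Decimal rounding helpers.

Printed monitoring tables round half-away-from-zero at a fixed number of
decimals.  Rounding is applied to the shortest decimal representation of the
float (``repr``) rather than its binary expansion, so values like 20.655
round to 20.7 instead of tripping over 20.65499...
"""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_away"]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties going away from zero."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))
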