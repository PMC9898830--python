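"""Currency display helpers.

All monetary quantities are carried at full float precision through the
pipeline; rounding to cents happens only at display/report boundaries,
with ties rounded away from zero (so 18.495 displays as 18.50).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def display_cents(value: float) -> float:
    """Round a dollar amount to 2 decimals, ties away from zero.

    Uses the shortest decimal representation of the float so that values
    like 18.495 (stored as the nearest binary float) still round up.
    """
    return float(Decimal(repr(float(value))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def format_usd(value: float) -> str:
    """Format a dollar amount as a 2-decimal string, e.g. '610.60'."""
    return f"{display_cents(value):.2f}"
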