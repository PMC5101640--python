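"""Small display/reporting helpers shared by the results objects and CLI."""

from __future__ import annotations

import decimal

__all__ = ["round_half_up"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero upward, matching the "30(37 %)" style of
    integer percentages in veterinary reports (banker's rounding would turn
    0.5 cases the wrong way)."""
    q = decimal.Decimal(10) ** -ndigits
    r = decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return int(r) if ndigits == 0 else float(r)
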