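"""Small shared helpers."""

from __future__ import annotations

import decimal


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimals.

    Printed-table comparisons use this convention (23.94, 26.21-style cells);
    binary floats make the builtin ``round`` unreliable at .5 boundaries.
    """
    q = decimal.Decimal(10) ** -ndigits
    d = decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def eur_to_usd(value_eur: float, rate: float) -> float:
    return value_eur * rate
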