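"""Display rounding shared by the frequency and hydrolysis statistics.

All statistics are kept as exact rationals internally; reports print them
at four decimal places using banker's (round-half-even) rounding.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_EVEN, localcontext
from fractions import Fraction

_QUANTUM = Decimal("0.0001")


def format4(value: Fraction | int | float | Decimal) -> str:
    """Render ``value`` with exactly four decimal places.

    Fractions are converted through :class:`~decimal.Decimal` at high
    precision so the rounding decision is made on the exact rational value,
    never on a binary-float approximation.
    """
    with localcontext() as ctx:
        ctx.prec = 60
        if isinstance(value, Fraction):
            dec = Decimal(value.numerator) / Decimal(value.denominator)
        elif isinstance(value, Decimal):
            dec = value
        elif isinstance(value, int):
            dec = Decimal(value)
        else:
            dec = Decimal(repr(float(value)))
        return str(dec.quantize(_QUANTUM, rounding=ROUND_HALF_EVEN))


def float4(value: Fraction | int | float | Decimal) -> float:
    """``format4`` as a float, for numeric report columns."""
    return float(format4(value))
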