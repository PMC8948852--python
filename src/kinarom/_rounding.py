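"""Decimal rounding helpers.

Python's built-in round() is banker's rounding; clinical tables in this
domain are printed with half-up rounding (and, for relative errors,
truncation), so both are provided explicitly. Decimal arithmetic on the
repr of the float avoids binary-representation artefacts such as
0.549/30*100 -> 1.8299999... truncating to 1.82.
"""

from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def truncate(value: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_DOWN))
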