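"""Small numeric helpers."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(value: float, decimals: int = 3) -> float:
    """Round to ``decimals`` places, halves away from zero.

    Display rounding throughout the package; classification always
    compares unrounded values.
    """
    q = Decimal(1).scaleb(-decimals)
    d = Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)
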