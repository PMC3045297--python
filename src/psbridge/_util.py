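"""Small numeric helpers shared across modules."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round1(x: float) -> float:
    """Round to one decimal, halves away from zero.

    Matches the reporting convention of the summary tables; plain ``round``
    (banker's rounding) would disagree on exact halves.
    """
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
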