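"""Small numeric helpers shared across the package."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` with ties going away from zero (half-up).

    Copy numbers and HL values are reported with conventional half-up
    rounding, not banker's rounding, so 1.835 -> 1.84 and 0.5 -> 1.
    ``repr`` is used to sidestep binary-float artefacts such as
    ``1.835 * 100 == 183.49999...``.
    """
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def round_copies(x: float) -> int:
    """Half-up rounding to whole molecule copies."""
    return int(round_half_up(x, 0))
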