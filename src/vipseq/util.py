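"""Small shared helpers."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_sig(x: float, n_sig: int) -> float:
    """Round ``x`` to ``n_sig`` significant figures, half away from zero.

    Human-readable reports print rates and titres at the precision the
    quantities warrant (full precision is always kept in TSV output).
    Decimal half-up matches how such values are conventionally printed:
    0.975 at two significant figures is 0.98, not the float-default 0.97.
    """
    x = float(x)
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    quantum = Decimal(1).scaleb(exponent - n_sig + 1)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))
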