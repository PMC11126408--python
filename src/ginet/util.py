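"""Small shared helpers."""
from __future__ import annotations

import math


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the given decimal place.

    Matches the printing convention used throughout the reporting tables
    (numpy/python banker's rounding would print 0.125 -> 0.12).
    """
    factor = 10.0**ndigits
    r = math.floor(abs(x) * factor + 0.5) / factor
    r = math.copysign(r, x)
    return r if ndigits > 0 else int(r)
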