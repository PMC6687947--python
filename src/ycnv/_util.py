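"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero.

    Python's built-in ``round`` uses banker's rounding; copy-number
    conventions here round 0.5 up (and -0.5 down).
    """
    if x >= 0:
        return int(math.floor(x + 0.5))
    return int(math.ceil(x - 0.5))


def round_cn(x: float) -> int:
    """Round a copy-number estimate to a non-negative integer."""
    return max(0, round_half_away(x))
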