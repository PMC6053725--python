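"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves going up.

    Used wherever a fraction of a count is turned into a count (top-k%
    feature selection, train/test sizing, top-expressed pools), so that
    e.g. 5% of 468 -> 23, 40% of 114 -> 46, 30% of 84 -> 25.
    """
    return int(math.floor(x + 0.5))


def clip_interval(start: int, end: int, lo: int, hi: int) -> tuple[int, int]:
    """Clip [start, end) to [lo, hi); may return an empty interval."""
    return max(start, lo), min(end, hi)
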