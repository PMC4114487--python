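"""Small shared numeric helpers."""

from __future__ import annotations

import math


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (18.75 -> 18.8 at one decimal).

    Python's round() rounds half to even; summary percentages follow the
    round-half-away-from-zero convention instead.
    """
    if not math.isfinite(x):
        return x
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def format_fold(fold: float) -> str:
    """Print a fold change: integer when >= 10, else one decimal."""
    if math.isinf(fold):
        return "inf"
    if fold >= 10:
        return str(int(round_half_away(fold, 0)))
    return f"{round_half_away(fold, 1):.1f}"
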