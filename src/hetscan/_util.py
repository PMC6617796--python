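"""Small shared helpers."""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (display convention for top-% values).

    Python's builtin ``round`` uses banker's rounding; report tables round
    half up, so 20.65 -> 20.7 rather than 20.6.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def competition_rank(values: np.ndarray, v: float) -> int:
    """1-based competition rank of ``v`` among ``values`` (largest = 1).

    Ties share the smallest rank: rank = 1 + #{values strictly greater}.
    """
    values = np.asarray(values, dtype=float)
    return 1 + int(np.sum(values > v))
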