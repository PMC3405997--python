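"""Small shared numeric helpers."""

from __future__ import annotations


def percent(count: float, total: float, decimals: int = 1) -> float:
    """Percentage of ``count`` in ``total`` on the 0-100 scale.

    Rounded to ``decimals`` places (default one decimal, the convention used
    for occupancy fractions and alignment rates throughout the package).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)


def fold_ratio(a: float, b: float, decimals: int | None = 1) -> float:
    """Fold difference a/b, optionally rounded (``decimals=None`` disables)."""
    if b <= 0:
        raise ValueError("denominator must be positive")
    r = a / b
    return r if decimals is None else round(r, decimals)
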