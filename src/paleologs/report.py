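"""Small reporting helpers shared by the pipeline outputs."""

from __future__ import annotations

__all__ = ["percent", "format_proportion"]


def percent(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Proportion as a percentage rounded to ``ndigits`` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("proportion with zero denominator")
    return round(100.0 * numerator / denominator, ndigits)


def format_proportion(numerator: int, denominator: int, ndigits: int = 2) -> str:
    """Render a count as ``'87/146 (59.59%)'`` style text."""
    value = percent(numerator, denominator, ndigits)
    # trim trailing zeros the way prose reports do (28%, not 28.00%)
    text = f"{value:.{ndigits}f}".rstrip("0").rstrip(".")
    return f"{numerator}/{denominator} ({text}%)"
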