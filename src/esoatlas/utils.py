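"""Small shared helpers."""

from __future__ import annotations

__all__ = ["percent_of"]


def percent_of(part: float, whole: float, decimals: int | None = None) -> float:
    """``100 * part / whole``, optionally rounded — e.g. the share of cells
    assigned to prevalent subsets, or a doublet-to-singlet ratio."""
    if whole == 0:
        raise ZeroDivisionError("whole is zero")
    pct = 100.0 * part / whole
    return round(pct, decimals) if decimals is not None else pct
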