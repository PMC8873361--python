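"""Shared statistical primitives: BH step-up correction and display rounding."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["bh_adjust", "round_half_away", "percentage"]


def bh_adjust(pvals) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1, rank-monotone)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out.tolist()


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (display convention for percentages)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percentage(count: float, total: float, ndigits: int = 1) -> float:
    """count/total as a percentage, rounded half-away-from-zero."""
    if total == 0:
        raise ValueError("total must be non-zero")
    return round_half_away(100.0 * count / total, ndigits)
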