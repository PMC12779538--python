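"""Largest-remainder (Hamilton) apportionment of an integer total over weights."""

from __future__ import annotations

import numpy as np


def largest_remainder(weights, total: int) -> np.ndarray:
    """Split ``total`` into integers proportional to ``weights``.

    Floors the exact quotas, then hands the remaining units to the cells with
    the largest fractional parts (ties broken by position, so the result is
    deterministic). Each cell is within 1 of its exact quota.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError("weights must be a non-empty 1-d array")
    if (w < 0).any() or not np.isfinite(w).all():
        raise ValueError("weights must be finite and non-negative")
    s = w.sum()
    if s <= 0:
        raise ValueError("weights must have a positive sum")
    if total < 0 or int(total) != total:
        raise ValueError("total must be a non-negative integer")
    quotas = total * (w / s)
    base = np.floor(quotas).astype(np.int64)
    short = int(total - base.sum())
    if short:
        order = np.argsort(-(quotas - base), kind="stable")
        base[order[:short]] += 1
    return base
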