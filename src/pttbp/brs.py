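"""Dynamic baroreflex sensitivity (BRS) by the sliding-window sequence
method.

BRS (ms/mmHg) quantifies how strongly beat-to-beat RR-interval changes
track same-direction SBP changes.  For each 16-point window over the
first-order forward differences (dRRi, dSBP), pairs with both
differences negative and pairs with both positive are collected
separately; within each set the OLS regression slope of dRRi on dSBP is
computed, and the window's BRS is the mean of the two slopes.  Windows
slide by one beat.

Degenerate windows: if one quadrant has fewer than 2 pairs (or zero
dSBP variance), the other quadrant's slope alone is used; if both are
degenerate the window is flagged invalid (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BRSSeries", "first_difference", "dynamic_brs"]


@dataclass
class BRSSeries:
    """Per-window BRS with diagnostics.

    ``window_start`` indexes the window's first beat in the original
    beat series (difference pair d_i pairs beats i and i+1, so window w
    spans beats w .. w+window).
    """

    window_start: np.ndarray
    brs: np.ndarray  # ms/mmHg; NaN where invalid
    n_q1: np.ndarray  # pairs with dRRi < 0 and dSBP < 0
    n_q3: np.ndarray  # pairs with dRRi > 0 and dSBP > 0
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.brs)


def first_difference(series: np.ndarray) -> np.ndarray:
    """First-order forward difference, d_i = x_{i+1} - x_i."""
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 points to difference")
    return np.diff(x)


def _quadrant_slope(drri: np.ndarray, dsbp: np.ndarray) -> float | None:
    """OLS slope of dRRi on dSBP, or None if < 2 pairs / zero variance."""
    if len(dsbp) < 2:
        return None
    sxx = np.sum((dsbp - dsbp.mean()) ** 2)
    if sxx <= 0:
        return None
    return float(np.sum((dsbp - dsbp.mean()) * (drri - drri.mean())) / sxx)


def dynamic_brs(
    rri: np.ndarray,
    sbp: np.ndarray,
    window: int = 16,
    step: int = 1,
) -> BRSSeries:
    """Sliding-window two-quadrant regression BRS.

    ``rri`` in ms and ``sbp`` in mmHg must have equal lengths of at
    least ``window + 1`` beats.  Zero differences join neither quadrant
    (strict sign conditions).
    """
    rri = np.asarray(rri, dtype=float)
    sbp = np.asarray(sbp, dtype=float)
    if len(rri) != len(sbp):
        raise ValueError("rri and sbp must have equal lengths")
    if len(rri) < window + 1:
        raise ValueError(f"need at least window+1 = {window + 1} beats")
    if window < 2 or step < 1:
        raise ValueError("window must be >= 2 and step >= 1")
    drri = first_difference(rri)
    dsbp = first_difference(sbp)
    n_windows = len(drri) - window + 1
    starts = np.arange(0, n_windows, step)
    brs = np.full(len(starts), np.nan)
    n_q1 = np.zeros(len(starts), dtype=int)
    n_q3 = np.zeros(len(starts), dtype=int)
    valid = np.zeros(len(starts), dtype=bool)
    for j, w in enumerate(starts):
        dr = drri[w: w + window]
        ds = dsbp[w: w + window]
        q1 = (dr < 0) & (ds < 0)
        q3 = (dr > 0) & (ds > 0)
        n_q1[j], n_q3[j] = int(q1.sum()), int(q3.sum())
        r1 = _quadrant_slope(dr[q1], ds[q1])
        r2 = _quadrant_slope(dr[q3], ds[q3])
        slopes = [r for r in (r1, r2) if r is not None]
        if slopes:
            brs[j] = float(np.mean(slopes))
            valid[j] = True
    return BRSSeries(
        window_start=starts,
        brs=brs,
        n_q1=n_q1,
        n_q3=n_q3,
        valid=valid,
    )
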