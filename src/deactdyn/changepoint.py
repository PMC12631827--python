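"""Exact dynamic-programming segmentation of 1D curves under an L1 cost.

Used to locate the temporal boundary in decoding time courses: the single
index that best splits the curve into two segments, where each segment's
cost is the summed absolute deviation from its median (robust to outliers,
sensitive to mean shifts).  The dynamic program returns the globally
optimal breakpoints for any requested number of segments, with ties broken
toward the earliest breakpoint so results are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["SegmentationResult", "BoundaryResult", "l1_cost", "dp_segment", "locate_boundary"]


@dataclass(frozen=True)
class SegmentationResult:
    """Optimal segmentation: each breakpoint is the first index of the next segment."""

    breakpoints: tuple[int, ...]
    total_cost: float
    segment_costs: tuple[float, ...]


@dataclass(frozen=True)
class BoundaryResult:
    """Located temporal boundary, in seconds relative to stimulus onset.

    ``reliable`` is False when the breakpoint lands on an edge of the
    admissible window — the fit was forced there by the window, not found.
    """

    time_s: float
    index: int
    reliable: bool
    segmentation: SegmentationResult


def l1_cost(signal: np.ndarray, start: int, end: int, min_size: int = 2) -> float:
    """Summed absolute deviation from the segment median on ``[start, end)``.

    The lower median is used for even-length segments; any value inside the
    median interval yields the same cost, so the choice only pins a
    convention.
    """
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    if not 0 <= start < end <= n:
        raise ValueError(f"invalid segment [{start}, {end}) for length {n}")
    if end - start < min_size:
        raise ValueError(f"segment [{start}, {end}) shorter than min_size={min_size}")
    seg = np.sort(signal[start:end])
    med = seg[(len(seg) - 1) // 2]  # lower median
    return float(np.abs(seg - med).sum())


def dp_segment(signal: np.ndarray, n_bkps: int, min_size: int = 2) -> SegmentationResult:
    """Globally optimal L1 segmentation into ``n_bkps + 1`` segments.

    Exact dynamic programming over all admissible breakpoint placements;
    among cost-ties the earliest breakpoint(s) win.  Complexity is
    O(n_bkps * n^2) cost lookups with memoized O(L log L) segment costs —
    ample for decoding time courses of a few hundred samples.
    """
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    if n_bkps < 1:
        raise ValueError("n_bkps must be >= 1")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if n < (n_bkps + 1) * min_size:
        raise ValueError(
            f"signal of length {n} cannot hold {n_bkps + 1} segments of size >= {min_size}"
        )

    @lru_cache(maxsize=None)
    def cost(s: int, e: int) -> float:
        return l1_cost(signal, s, e, min_size=min_size)

    # best[k][e]: (cost, breakpoints) for segmenting signal[:e] into k+1 parts.
    # Ties are broken toward the earliest breakpoint.  L1 segmentations tie
    # exactly whenever boundary points lie between the two segment medians,
    # so the comparison uses a relative tolerance: otherwise rounding noise
    # (which shifting/scaling the signal perturbs) would decide such ties.
    tol = 1e-9
    best: dict[int, dict[int, tuple[float, tuple[int, ...]]]] = {
        0: {e: (cost(0, e), ()) for e in range(min_size, n + 1)}
    }
    for kk in range(1, n_bkps + 1):
        best[kk] = {}
        for e in range((kk + 1) * min_size, n + 1):
            best_c, best_b = np.inf, ()
            for t in range(kk * min_size, e - min_size + 1):
                prev_c, prev_b = best[kk - 1][t]
                c = prev_c + cost(t, e)
                if not np.isfinite(best_c) or c < best_c - tol * (1.0 + best_c):
                    best_c, best_b = c, prev_b + (t,)
            best[kk][e] = (best_c, best_b)

    total, bkps = best[n_bkps][n]
    bounds = (0,) + bkps + (n,)
    seg_costs = tuple(cost(s, e) for s, e in zip(bounds[:-1], bounds[1:]))
    return SegmentationResult(breakpoints=bkps, total_cost=float(total), segment_costs=seg_costs)


def locate_boundary(
    curve: np.ndarray,
    fs: float,
    window: tuple[float, float],
    min_size: int = 2,
    t0_s: float = 0.0,
) -> BoundaryResult:
    """Locate the single changepoint of a decoding curve within a time window.

    The curve is restricted to ``[t_lo, t_hi]`` (seconds relative to
    stimulus onset), segmented into exactly two parts, and the breakpoint
    converted back to seconds.  A breakpoint pinned against either window
    edge is flagged unreliable.
    """
    curve = np.asarray(curve, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    t_lo, t_hi = window
    if t_hi <= t_lo:
        raise ValueError("window must satisfy t_lo < t_hi")
    i_lo = int(round((t_lo - t0_s) * fs))
    i_hi = int(round((t_hi - t0_s) * fs))
    i_lo = max(i_lo, 0)
    i_hi = min(i_hi, len(curve))
    sub = curve[i_lo:i_hi]
    if len(sub) < 2 * min_size:
        raise ValueError(
            f"window holds {len(sub)} samples; need at least {2 * min_size} for two segments"
        )
    seg = dp_segment(sub, n_bkps=1, min_size=min_size)
    bk_local = seg.breakpoints[0]
    reliable = min_size < bk_local < len(sub) - min_size
    index = i_lo + bk_local
    return BoundaryResult(
        time_s=t0_s + index / fs, index=index, reliable=reliable, segmentation=seg
    )
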