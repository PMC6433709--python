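"""Small utilities for 0-based half-open genomic intervals.

All functions operate on plain ``(start, end)`` tuples or Nx2 integer
arrays; chromosome bookkeeping is left to callers.
"""

from __future__ import annotations

import numpy as np


def merge(intervals):
    """Merge overlapping or book-ended intervals.

    Parameters
    ----------
    intervals : iterable of (start, end)

    Returns
    -------
    list of (start, end), sorted and disjoint.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def subtract(intervals, others):
    """Set-subtract ``others`` from ``intervals`` (both merged internally)."""
    a = merge(intervals)
    b = merge(others)
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def clip(intervals, lo, hi):
    """Clip intervals to [lo, hi), dropping empties."""
    out = []
    for s, e in intervals:
        s2, e2 = max(s, lo), min(e, hi)
        if e2 > s2:
            out.append((s2, e2))
    return out


def total_length(intervals):
    return sum(e - s for s, e in merge(intervals))


class MembershipIndex:
    """O(log n) point-membership queries against a merged interval set."""

    def __init__(self, intervals):
        ivs = merge(intervals)
        self.starts = np.array([s for s, _ in ivs], dtype=np.int64)
        self.ends = np.array([e for _, e in ivs], dtype=np.int64)

    def contains(self, pos):
        """Vectorized membership for 0-based positions."""
        pos = np.asarray(pos, dtype=np.int64)
        if self.starts.size == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(self.starts, pos, side="right") - 1
        ok = idx >= 0
        res = np.zeros(pos.shape, dtype=bool)
        res[ok] = pos[ok] < self.ends[idx[ok]]
        return res
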