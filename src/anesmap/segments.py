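"""Half-open time-interval arithmetic.

Segments are ``(n, 2)`` float arrays of ``[start_s, end_s)`` rows, sorted and
pairwise disjoint.  All segmentation outputs of the package (IES, theta/delta
suppressions, planted ground-truth intervals, gamma runs) use this
representation, so the interval operations here are exact (no sampling grid
involved).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "as_segments",
    "total_duration",
    "merge_close",
    "filter_min_duration",
    "intersect",
    "difference",
    "overlap_duration",
    "jaccard",
    "bool_runs",
]


def as_segments(segs: Iterable[Sequence[float]] | np.ndarray) -> np.ndarray:
    """Coerce to a sorted ``(n, 2)`` float array, validating start < end."""
    arr = np.asarray(list(segs), dtype=float).reshape(-1, 2)
    if arr.size and np.any(arr[:, 1] <= arr[:, 0]):
        raise ValueError("segments must satisfy start < end")
    if arr.size:
        arr = arr[np.argsort(arr[:, 0])]
    return arr


def total_duration(segs: np.ndarray) -> float:
    segs = as_segments(segs)
    return float(np.sum(segs[:, 1] - segs[:, 0])) if segs.size else 0.0


def merge_close(segs: np.ndarray, gap_s: float) -> np.ndarray:
    """Merge consecutive segments separated by a gap strictly below ``gap_s``."""
    segs = as_segments(segs)
    if len(segs) <= 1:
        return segs
    out = [list(segs[0])]
    for s, e in segs[1:]:
        if s - out[-1][1] < gap_s:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=float)


def filter_min_duration(segs: np.ndarray, min_dur_s: float) -> np.ndarray:
    segs = as_segments(segs)
    if not segs.size:
        return segs
    keep = (segs[:, 1] - segs[:, 0]) >= min_dur_s
    return segs[keep]


def intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise intersection of two disjoint sorted segment lists."""
    a, b = as_segments(a), as_segments(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if e > s:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return as_segments(out)


def difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Set difference ``a \\ b`` on half-open intervals (exact)."""
    a, b = as_segments(a), as_segments(b)
    if not a.size or not b.size:
        return a
    out = []
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, min(bs, e)))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return as_segments(out)


def overlap_duration(segs: np.ndarray, start: float, end: float) -> float:
    """Total duration of ``segs`` falling inside ``[start, end)``."""
    segs = as_segments(segs)
    if not segs.size:
        return 0.0
    lo = np.maximum(segs[:, 0], start)
    hi = np.minimum(segs[:, 1], end)
    return float(np.sum(np.maximum(hi - lo, 0.0)))


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index |a n b| / |a u b| of two segment lists (1.0 if both empty)."""
    inter = total_duration(intersect(a, b))
    union = total_duration(a) + total_duration(b) - inter
    if union <= 0:
        return 1.0
    return inter / union


def bool_runs(mask: np.ndarray) -> np.ndarray:
    """Maximal runs of True in a boolean array, as ``(n, 2)`` index pairs
    with half-open sample indices ``[i0, i1)``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return np.empty((0, 2), dtype=int)
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return np.column_stack([starts, ends])
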