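"""Half-open interval arithmetic on sorted integer arrays.

All genomic intervals in this package are 0-based half-open ``[start, end)``
and are stored per contig as ``(n, 2)`` int64 numpy arrays. The functions
here normalize (sort + merge), intersect, and rasterize such arrays; they are
the single code path behind callable masks, HCR tiles, and gene overlap.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "merge",
    "intersect",
    "total_length",
    "to_bool",
    "from_bool",
    "is_normalized",
]


def merge(intervals: np.ndarray | list) -> np.ndarray:
    """Sort and merge overlapping or adjacent half-open intervals.

    Adjacent intervals ([0,10) + [10,20)) are coalesced, so the result is
    the minimal normalized representation of the covered set.
    """
    arr = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if np.any(arr[:, 0] >= arr[:, 1]):
        bad = arr[arr[:, 0] >= arr[:, 1]][0]
        raise ValueError(f"empty or inverted interval [{bad[0]}, {bad[1]})")
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = []
    cur_s, cur_e = arr[0]
    for s, e in arr[1:]:
        if s <= cur_e:  # overlap or adjacency
            cur_e = max(cur_e, e)
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    out.append((cur_s, cur_e))
    return np.array(out, dtype=np.int64)


def is_normalized(arr: np.ndarray) -> bool:
    arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
    if arr.shape[0] == 0:
        return True
    if np.any(arr[:, 0] >= arr[:, 1]):
        return False
    return bool(np.all(arr[1:, 0] > arr[:-1, 1]))


def intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two normalized interval arrays (two-pointer sweep)."""
    a = np.asarray(a, dtype=np.int64).reshape(-1, 2)
    b = np.asarray(b, dtype=np.int64).reshape(-1, 2)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def total_length(arr: np.ndarray) -> int:
    arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
    if arr.size == 0:
        return 0
    return int(np.sum(arr[:, 1] - arr[:, 0]))


def to_bool(arr: np.ndarray, length: int, start: int = 0) -> np.ndarray:
    """Rasterize intervals onto a boolean array covering [start, start+length)."""
    out = np.zeros(length, dtype=bool)
    arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
    for s, e in arr:
        s = max(s - start, 0)
        e = min(e - start, length)
        if s < e:
            out[s:e] = True
    return out


def from_bool(mask: np.ndarray, start: int = 0) -> np.ndarray:
    """Inverse of :func:`to_bool`: extract normalized intervals from a bool array."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0 or not mask.any():
        return np.zeros((0, 2), dtype=np.int64)
    diff = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        ends = np.concatenate((ends, [mask.size]))
    return np.column_stack((starts + start, ends + start)).astype(np.int64)
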