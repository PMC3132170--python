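"""Small interval utilities: merging, clipped union length, overlap tests.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from typing import Iterable, Sequence


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching ``(start, end)`` intervals.

    Empty (start == end) intervals are dropped.
    """
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def union_length_in_window(
    intervals: Iterable[tuple[int, int]], window_start: int, window_end: int
) -> int:
    """Length of the union of ``intervals`` clipped to ``[window_start, window_end)``."""
    total = 0
    for s, e in merge_intervals(intervals):
        lo = max(s, window_start)
        hi = min(e, window_end)
        if hi > lo:
            total += hi - lo
    return total


def covered_fraction(
    intervals: Iterable[tuple[int, int]], window_start: int, window_end: int
) -> float:
    """Fraction of the window covered by the union of the intervals."""
    width = window_end - window_start
    if width <= 0:
        return 0.0
    return union_length_in_window(intervals, window_start, window_end) / width


def overlaps_any(
    start: int, end: int, intervals: Sequence[tuple[int, int]]
) -> bool:
    """True iff ``[start, end)`` intersects at least one interval by >= 1 bp.

    Zero-length query intervals never overlap anything.
    """
    if end <= start:
        return False
    return any(max(start, s) < min(end, e) for s, e in intervals)
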