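"""Half-open integer interval tuples used for read/fragment coverage.

Coverage of a read is almost always a single contiguous interval (deleted
reference positions count as covered), so sets of positions are stored as
sorted, disjoint ``(start, end)`` pairs instead of explicit position sets.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Intervals = tuple[tuple[int, int], ...]


def merge(spans: Iterable[tuple[int, int]]) -> Intervals:
    """Sort, drop empties, and coalesce touching/overlapping spans."""
    spans = sorted((s, e) for s, e in spans if e > s)
    out: list[tuple[int, int]] = []
    for s, e in spans:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return tuple(out)


def union(a: Iterable[tuple[int, int]], b: Iterable[tuple[int, int]]) -> Intervals:
    return merge(list(a) + list(b))


def contains(iv: Intervals, pos: int) -> bool:
    for s, e in iv:
        if s <= pos < e:
            return True
        if pos < s:
            return False
    return False


def contains_all(iv: Intervals, positions: Iterable[int]) -> bool:
    return all(contains(iv, p) for p in positions)


def contains_span(iv: Intervals, start: int, end: int) -> bool:
    """True if [start, end) lies inside a single stored interval."""
    if end <= start:
        return True
    for s, e in iv:
        if s <= start and end <= e:
            return True
    return False


def length(iv: Intervals) -> int:
    return sum(e - s for s, e in iv)


def overlap_length(a: Intervals, b: Intervals) -> int:
    total = 0
    for s1, e1 in a:
        for s2, e2 in b:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def positions(iv: Intervals) -> list[int]:
    out: list[int] = []
    for s, e in iv:
        out.extend(range(s, e))
    return out


def from_positions(pos: Sequence[int]) -> Intervals:
    return merge((p, p + 1) for p in pos)
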