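"""Small interval-arithmetic helpers on (start, end) half-open tuples.

All functions take and return plain lists of ``(start, end)`` int tuples;
chromosome bookkeeping is the caller's job.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge(intervals: Iterable[Interval], gap: int = 0) -> list[Interval]:
    """Union of intervals, merging any pair separated by at most ``gap``."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s - out[-1][1] <= gap:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Intersection of two interval unions (each assumed merged & sorted)."""
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals))


def contains(container: Sequence[Interval], start: int, end: int) -> bool:
    """True iff [start, end) is fully covered by the (merged) union."""
    for s, e in merge(container):
        if s <= start and end <= e:
            return True
    return False


def covered_at_least(unions: Sequence[Sequence[Interval]], k: int
                     ) -> list[Interval]:
    """Region covered by at least ``k`` of the given interval unions."""
    events: list[tuple[int, int]] = []
    for u in unions:
        for s, e in merge(u):
            events.append((s, 1))
            events.append((e, -1))
    events.sort()
    out: list[Interval] = []
    depth = 0
    open_at: int | None = None
    for pos, delta in events:
        prev = depth
        depth += delta
        if prev < k <= depth:
            open_at = pos
        elif prev >= k > depth and open_at is not None:
            if pos > open_at:
                out.append((open_at, pos))
            open_at = None
    return merge(out)
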