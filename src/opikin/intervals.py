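"""Half-open interval algebra on the time axis.

All intervals are ``[start, end)`` in seconds from case start.  Using half-open
spans makes union / intersection / total-duration arithmetic exact: adjacent
spans ``[a, b)`` and ``[b, c)`` tile ``[a, c)`` without double counting the
boundary sample.
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

Interval = Tuple[float, float]


def normalize(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and merge overlapping or adjacent half-open intervals.

    Empty or inverted spans (``end <= start``) are dropped.  The result is a
    minimal, sorted, pairwise-disjoint cover of the same point set.
    """
    ivs = sorted((float(s), float(e)) for s, e in intervals if float(e) > float(s))
    out: List[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Intersection of two interval sets (each normalized internally)."""
    a = normalize(a)
    b = normalize(b)
    out: List[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total(intervals: Iterable[Interval]) -> float:
    """Total length covered by a set of disjoint intervals, in seconds."""
    return float(sum(e - s for s, e in intervals))


def union_duration(intervals: Iterable[Interval]) -> float:
    """Total length covered by an arbitrary (possibly overlapping) set."""
    return total(normalize(intervals))


def clip_to(intervals: Iterable[Interval], window: Interval) -> List[Interval]:
    """Restrict an interval set to a single window."""
    return intersect(intervals, [window])
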