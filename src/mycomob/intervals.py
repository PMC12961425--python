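"""Half-open integer interval sets.

All coordinate logic in the toolkit runs on 0-based half-open intervals
``[s, e)`` over a single axis (a consensus sequence or a genomic contig).
:class:`IntervalSet` keeps its intervals sorted and pairwise disjoint;
touching intervals are merged on construction, so the representation of a
covered region is canonical and set operations stay linear-time sweeps.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Tuple

Span = Tuple[int, int]


def normalize(spans: Iterable[Span]) -> list[Span]:
    """Sort spans and merge any that overlap or touch.

    Raises ``ValueError`` for empty or inverted spans.
    """
    cleaned = []
    for s, e in spans:
        s, e = int(s), int(e)
        if s >= e:
            raise ValueError(f"invalid interval [{s}, {e}): start must be < end")
        cleaned.append((s, e))
    cleaned.sort()
    merged: list[Span] = []
    for s, e in cleaned:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


class IntervalSet:
    """A normalized set of disjoint, sorted half-open intervals."""

    __slots__ = ("_spans",)

    def __init__(self, spans: Iterable[Span] = ()):
        self._spans: tuple[Span, ...] = tuple(
            (s, e) for s, e in normalize(list(spans))
        )

    @property
    def intervals(self) -> tuple[Span, ...]:
        return self._spans

    def total_length(self) -> int:
        return sum(e - s for s, e in self._spans)

    def __bool__(self) -> bool:
        return bool(self._spans)

    def __len__(self) -> int:
        return len(self._spans)

    def __iter__(self) -> Iterator[Span]:
        return iter(self._spans)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._spans == other._spans

    def __hash__(self) -> int:
        return hash(self._spans)

    def __repr__(self) -> str:
        inner = ", ".join(f"[{s},{e})" for s, e in self._spans)
        return f"IntervalSet({{{inner}}})"

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(list(self._spans) + list(other._spans))

    __or__ = union

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: list[Span] = []
        a, b = self._spans, other._spans
        i = j = 0
        while i < len(a) and j < len(b):
            s = max(a[i][0], b[j][0])
            e = min(a[i][1], b[j][1])
            if s < e:
                out.append((s, e))
            if a[i][1] <= b[j][1]:
                i += 1
            else:
                j += 1
        return IntervalSet(out)

    __and__ = intersect

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        out: list[Span] = []
        cuts = other._spans
        j = 0
        for s, e in self._spans:
            cur = s
            while j < len(cuts) and cuts[j][1] <= cur:
                j += 1
            k = j
            while k < len(cuts) and cuts[k][0] < e:
                cs, ce = cuts[k]
                if cs > cur:
                    out.append((cur, cs))
                cur = max(cur, ce)
                if ce >= e:
                    break
                k += 1
            if cur < e:
                out.append((cur, e))
        return IntervalSet(out)

    __sub__ = subtract

    def contains_point(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self._spans)


def merge_with_gap(spans: Iterable[Span], gap_max: int) -> IntervalSet:
    """Coalesce spans that overlap, touch, or are separated by ``<= gap_max``.

    ``gap_max = 0`` reduces to the plain union (touching intervals merge).
    """
    if gap_max < 0:
        raise ValueError("gap_max must be >= 0")
    spans = sorted((int(s), int(e)) for s, e in spans)
    merged: list[Span] = []
    for s, e in spans:
        if merged and s - merged[-1][1] <= gap_max:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return IntervalSet(merged)
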