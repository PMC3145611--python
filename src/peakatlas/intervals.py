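"""Genomic interval primitives.

Every module in the toolkit consumes and emits plain peak lists. The two
central containers are :class:`GenomicInterval` (0-based, half-open) and
:class:`PeakSet` (intervals grouped by chromosome). Fast all-overlap queries
go through :class:`IntervalTree`, an augmented binary search tree in which
each node additionally stores the maximum end coordinate of its subtree,
allowing subtrees that cannot contain an overlap to be pruned while still
reporting *every* overlapping interval, not just the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    id: Optional[str] = None
    score: Optional[float] = None
    extra: tuple = ()

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strict positive-width intersection; abutting intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between two intervals; 0 if they overlap or abut."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        if self.start < other.end and other.start < self.end:
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


class PeakSet:
    """An ordered collection of intervals grouped by chromosome.

    Duplicate identical intervals are permitted and counted as distinct
    peaks everywhere.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        source: str = "",
    ) -> None:
        self.source = source
        self._by_chrom: Dict[str, List[GenomicInterval]] = {}
        for iv in intervals:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self.chromosomes:
            yield from self._by_chrom[chrom]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return sorted(self.coords()) == sorted(other.coords())

    def __repr__(self) -> str:
        return f"PeakSet({len(self)} peaks on {len(self._by_chrom)} chromosomes)"

    # -- accessors ----------------------------------------------------------
    @property
    def chromosomes(self) -> List[str]:
        return sorted(self._by_chrom)

    def on(self, chrom: str) -> List[GenomicInterval]:
        return self._by_chrom.get(chrom, [])

    def coords(self) -> List[tuple]:
        return [(iv.chrom, iv.start, iv.end) for iv in self]

    def sorted(self) -> "PeakSet":
        return PeakSet(
            (
                iv
                for chrom in self.chromosomes
                for iv in sorted(self.on(chrom), key=lambda i: (i.start, i.end))
            ),
            source=self.source,
        )

    def add(self, iv: GenomicInterval) -> None:
        self._by_chrom.setdefault(iv.chrom, []).append(iv)

    def has_duplicates(self) -> bool:
        coords = self.coords()
        return len(coords) != len(set(coords))


# ---------------------------------------------------------------------------
# Augmented interval tree
# ---------------------------------------------------------------------------


@dataclass
class _Node:
    interval: GenomicInterval
    max_end: int
    left: Optional["_Node"] = None
    right: Optional["_Node"] = None


class IntervalTree:
    """Per-chromosome augmented binary search tree keyed by interval start.

    Each node stores the maximum end coordinate over its subtree so a query
    can skip any subtree whose ``max_end`` does not reach the query start.
    The query reports *all* stored intervals with positive-width overlap.
    """

    def __init__(self, peaks: Optional[PeakSet] = None) -> None:
        self._roots: Dict[str, Optional[_Node]] = {}
        self._n = 0
        if peaks is not None:
            for chrom in peaks.chromosomes:
                # build balanced from sorted intervals
                ivs = sorted(peaks.on(chrom), key=lambda i: (i.start, i.end))
                self._roots[chrom] = self._build(ivs)
                self._n += len(ivs)

    def _build(self, ivs: Sequence[GenomicInterval]) -> Optional[_Node]:
        if not ivs:
            return None
        mid = len(ivs) // 2
        node = _Node(ivs[mid], ivs[mid].end)
        node.left = self._build(ivs[:mid])
        node.right = self._build(ivs[mid + 1 :])
        for child in (node.left, node.right):
            if child is not None:
                node.max_end = max(node.max_end, child.max_end)
        return node

    def __len__(self) -> int:
        return self._n

    def insert(self, iv: GenomicInterval) -> None:
        self._roots[iv.chrom] = self._insert(self._roots.get(iv.chrom), iv)
        self._n += 1

    def _insert(self, node: Optional[_Node], iv: GenomicInterval) -> _Node:
        if node is None:
            return _Node(iv, iv.end)
        node.max_end = max(node.max_end, iv.end)
        if (iv.start, iv.end) < (node.interval.start, node.interval.end):
            node.left = self._insert(node.left, iv)
        else:
            node.right = self._insert(node.right, iv)
        return node

    def query(self, q: GenomicInterval) -> List[GenomicInterval]:
        """All stored intervals overlapping ``q`` (half-open semantics)."""
        out: List[GenomicInterval] = []
        root = self._roots.get(q.chrom)
        if root is None:
            return out
        stack = [root]
        while stack:
            node = stack.pop()
            if node.max_end <= q.start:
                continue  # no interval below can reach q
            if node.left is not None:
                stack.append(node.left)
            iv = node.interval
            if iv.start < q.end and q.start < iv.end:
                out.append(iv)
            # right subtree has starts >= node start; prune if beyond q end
            if node.right is not None and node.interval.start < q.end:
                stack.append(node.right)
        return out

    def any_overlap(self, q: GenomicInterval) -> bool:
        root = self._roots.get(q.chrom)
        if root is None:
            return False
        stack = [root]
        while stack:
            node = stack.pop()
            if node.max_end <= q.start:
                continue
            iv = node.interval
            if iv.start < q.end and q.start < iv.end:
                return True
            if node.left is not None:
                stack.append(node.left)
            if node.right is not None and node.interval.start < q.end:
                stack.append(node.right)
        return False

    def intervals(self) -> List[GenomicInterval]:
        """In-order traversal over all chromosomes (sorted by start)."""
        out: List[GenomicInterval] = []
        for chrom in sorted(self._roots):
            stack: List[_Node] = []
            node = self._roots[chrom]
            while stack or node:
                while node:
                    stack.append(node)
                    node = node.left
                node = stack.pop()
                out.append(node.interval)
                node = node.right
        return out

    def check_augmentation(self) -> bool:
        """Verify every node's stored max equals max(end) over its subtree."""

        def rec(node: Optional[_Node]) -> Optional[int]:
            if node is None:
                return None
            m = node.interval.end
            for child in (node.left, node.right):
                cm = rec(child)
                if cm is not None:
                    m = max(m, cm)
            if m != node.max_end:
                raise AssertionError(
                    f"augmentation broken at {node.interval}: "
                    f"stored {node.max_end}, actual {m}"
                )
            return m

        for root in self._roots.values():
            rec(root)
        return True


def build_tree(peaks: PeakSet) -> IntervalTree:
    """Index a peak set for all-overlap queries."""
    return IntervalTree(peaks)


def query_all_overlaps(tree: IntervalTree, q: GenomicInterval) -> List[GenomicInterval]:
    return tree.query(q)
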