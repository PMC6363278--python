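"""Sorted, merged genomic interval sets with base-pair set algebra.

A :class:`GenomicIntervalSet` stores, per chromosome, a ``(N, 2)`` int64
array of 0-based half-open ``[start, end)`` intervals. Intervals are
normalised on construction: sorted, with overlapping *or touching*
intervals merged, so every instance represents a base-pair coverage set
uniquely.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping

import numpy as np

Interval = tuple[str, int, int]


def _merge(arr: np.ndarray) -> np.ndarray:
    """Sort and merge an (N, 2) interval array (touching intervals merge)."""
    if arr.size == 0:
        return arr.reshape(0, 2)
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


class GenomicIntervalSet:
    """A per-chromosome set of merged, sorted half-open intervals."""

    __slots__ = ("_data",)

    def __init__(self, intervals: Iterable[Interval] | Mapping[str, np.ndarray] | None = None):
        data: dict[str, np.ndarray] = {}
        if intervals is None:
            pass
        elif isinstance(intervals, Mapping):
            for chrom, arr in intervals.items():
                arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                self._check(chrom, arr)
                merged = _merge(arr)
                if merged.size:
                    data[chrom] = merged
        else:
            buckets: dict[str, list[tuple[int, int]]] = {}
            for chrom, start, end in intervals:
                self._check(chrom, np.asarray([[start, end]]))
                buckets.setdefault(str(chrom), []).append((int(start), int(end)))
            for chrom, ivs in buckets.items():
                merged = _merge(np.asarray(ivs, dtype=np.int64))
                if merged.size:
                    data[chrom] = merged
        self._data = dict(sorted(data.items()))

    @staticmethod
    def _check(chrom: str, arr: np.ndarray) -> None:
        if np.any(arr[:, 0] < 0):
            raise ValueError(f"negative coordinate on {chrom}")
        if np.any(arr[:, 0] >= arr[:, 1]):
            raise ValueError(f"empty or inverted interval on {chrom}")

    # -- basic introspection -------------------------------------------------

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._data)

    def intervals(self, chrom: str) -> np.ndarray:
        return self._data.get(chrom, np.empty((0, 2), dtype=np.int64))

    def __iter__(self) -> Iterator[Interval]:
        for chrom, arr in self._data.items():
            for s, e in arr:
                yield chrom, int(s), int(e)

    def __len__(self) -> int:
        return sum(len(a) for a in self._data.values())

    def __bool__(self) -> bool:
        return len(self) > 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomicIntervalSet):
            return NotImplemented
        if self.chroms != other.chroms:
            return False
        return all(np.array_equal(self._data[c], other._data[c]) for c in self._data)

    def __hash__(self):  # pragma: no cover - sets are mutable-ish containers
        raise TypeError("GenomicIntervalSet is unhashable")

    def __repr__(self) -> str:
        return f"GenomicIntervalSet({len(self)} intervals, {self.total_bp} bp)"

    @property
    def total_bp(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._data.values()))

    def lengths(self) -> np.ndarray:
        """All interval lengths, genome order."""
        if not self._data:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([a[:, 1] - a[:, 0] for a in self._data.values()])

    # -- set algebra ---------------------------------------------------------

    def union(self, other: "GenomicIntervalSet") -> "GenomicIntervalSet":
        data: dict[str, np.ndarray] = {}
        for chrom in sorted(set(self._data) | set(other._data)):
            arr = np.concatenate([self.intervals(chrom), other.intervals(chrom)])
            data[chrom] = _merge(arr)
        return GenomicIntervalSet(data)

    def intersection(self, other: "GenomicIntervalSet") -> "GenomicIntervalSet":
        data: dict[str, np.ndarray] = {}
        for chrom in set(self._data) & set(other._data):
            a, b = self._data[chrom], other._data[chrom]
            out = []
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    out.append((s, e))
                if a[i, 1] < b[j, 1]:
                    i += 1
                else:
                    j += 1
            if out:
                data[chrom] = np.asarray(out, dtype=np.int64)
        return GenomicIntervalSet(data)

    def difference(self, other: "GenomicIntervalSet") -> "GenomicIntervalSet":
        data: dict[str, np.ndarray] = {}
        for chrom, a in self._data.items():
            b = other.intervals(chrom)
            if b.size == 0:
                data[chrom] = a.copy()
                continue
            out = []
            j = 0
            for s, e in a:
                cur = s
                while j < len(b) and b[j, 1] <= cur:
                    j += 1
                k = j
                while k < len(b) and b[k, 0] < e:
                    if b[k, 0] > cur:
                        out.append((cur, b[k, 0]))
                    cur = max(cur, b[k, 1])
                    k += 1
                if cur < e:
                    out.append((cur, e))
            if out:
                data[chrom] = np.asarray(out, dtype=np.int64)
        return GenomicIntervalSet(data)

    def contains(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean membership of base positions in this coverage set."""
        arr = self.intervals(chrom)
        positions = np.asarray(positions)
        if arr.size == 0:
            return np.zeros(positions.shape, dtype=bool)
        idx = np.searchsorted(arr.ravel(), positions, side="right")
        return idx % 2 == 1

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Base pairs of ``[start, end)`` covered by this set."""
        arr = self.intervals(chrom)
        if arr.size == 0:
            return 0
        s = np.minimum(np.maximum(arr[:, 0], start), end)
        e = np.minimum(np.maximum(arr[:, 1], start), end)
        return int(np.maximum(e - s, 0).sum())
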