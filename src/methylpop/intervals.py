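"""Merged genomic interval sets with vectorized membership queries.

Coordinates are 1-based inclusive throughout (GFF3 convention).  Each scaffold
holds a merged, sorted array of (start, end) pairs; membership is a pair of
``searchsorted`` lookups, so annotating millions of sites stays cheap.
"""

from __future__ import annotations

import numpy as np


class IntervalSet:
    """Per-scaffold merged interval collection."""

    def __init__(self) -> None:
        self._raw: dict[str, list[tuple[int, int]]] = {}
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    @classmethod
    def from_intervals(cls, intervals) -> "IntervalSet":
        """Build from iterable of (scaffold, start, end)."""
        s = cls()
        for scaffold, start, end in intervals:
            s.add(scaffold, start, end)
        return s

    def add(self, scaffold: str, start: int, end: int) -> None:
        if end < start:
            return
        self._raw.setdefault(scaffold, []).append((int(start), int(end)))
        self._merged = None

    def _merge(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        if self._merged is None:
            merged = {}
            for scaffold, ivals in self._raw.items():
                ivals = sorted(ivals)
                starts, ends = [], []
                for s, e in ivals:
                    if ends and s <= ends[-1] + 1:
                        ends[-1] = max(ends[-1], e)
                    else:
                        starts.append(s)
                        ends.append(e)
                merged[scaffold] = (np.array(starts, dtype=np.int64),
                                    np.array(ends, dtype=np.int64))
            self._merged = merged
        return self._merged

    def contains(self, scaffold: str, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: which positions fall inside an interval on scaffold."""
        positions = np.asarray(positions, dtype=np.int64)
        merged = self._merge()
        if scaffold not in merged or positions.size == 0:
            return np.zeros(positions.shape, dtype=bool)
        starts, ends = merged[scaffold]
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(positions.shape, dtype=bool)
        out[ok] = positions[ok] <= ends[idx[ok]]
        return out

    def total_length(self) -> int:
        return int(sum((e - s + 1).sum() for s, e in self._merge().values()))

    def scaffolds(self) -> list[str]:
        return list(self._merge().keys())

    def intervals(self, scaffold: str) -> list[tuple[int, int]]:
        merged = self._merge()
        if scaffold not in merged:
            return []
        s, e = merged[scaffold]
        return list(zip(s.tolist(), e.tolist()))
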