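"""Half-open genomic interval sets with merge/intersect arithmetic.

All coordinates are 0-based half-open.  Intervals are merged and sorted on
construction, so a set is always a disjoint union; this is the container
behind SNP-density contrasts and the permutation enrichment test.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["IntervalSet", "read_bed", "write_bed"]


def _merge(pairs: np.ndarray) -> np.ndarray:
    if len(pairs) == 0:
        return np.zeros((0, 2), dtype=np.int64)
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    out = [list(pairs[0])]
    for a, b in pairs[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return np.asarray(out, dtype=np.int64)


class IntervalSet:
    """chrom -> (k, 2) arrays of disjoint sorted [start, end) intervals."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        grouped: dict[str, list[tuple[int, int]]] = {}
        for chrom, a, b in intervals:
            if not a < b:
                raise ValueError(f"empty or inverted interval [{a},{b}) on {chrom}")
            grouped.setdefault(chrom, []).append((int(a), int(b)))
        self.data: dict[str, np.ndarray] = {
            c: _merge(np.asarray(v, dtype=np.int64)) for c, v in sorted(grouped.items())
        }

    def __iter__(self):
        for chrom, arr in self.data.items():
            for a, b in arr:
                yield chrom, int(a), int(b)

    def __len__(self) -> int:
        return sum(len(v) for v in self.data.values())

    @property
    def total_length(self) -> int:
        return int(sum((v[:, 1] - v[:, 0]).sum() for v in self.data.values()))

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out = []
        for chrom in set(self.data) & set(other.data):
            a, b = self.data[chrom], other.data[chrom]
            i = j = 0
            while i < len(a) and j < len(b):
                lo = max(a[i, 0], b[j, 0])
                hi = min(a[i, 1], b[j, 1])
                if lo < hi:
                    out.append((chrom, int(lo), int(hi)))
                if a[i, 1] < b[j, 1]:
                    i += 1
                else:
                    j += 1
        return IntervalSet(out)

    def overlap_bp(self, other: "IntervalSet") -> int:
        return self.intersect(other).total_length

    def contains_points(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: which positions fall inside the set."""
        pos = np.asarray(pos, dtype=np.int64)
        arr = self.data.get(chrom)
        if arr is None or len(arr) == 0:
            return np.zeros(len(pos), dtype=bool)
        starts, ends = arr[:, 0], arr[:, 1]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        res = np.zeros(len(pos), dtype=bool)
        res[ok] = pos[ok] < ends[idx[ok]]
        return res


def read_bed(path) -> IntervalSet:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1]), int(f[2])))
    return IntervalSet(rows)


def write_bed(intervals: Sequence[tuple], path) -> None:
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")
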