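"""Sorted, merged, half-open genomic interval sets with exact bp algebra.

All coordinates are 0-based half-open. Construction always normalizes to
sorted, pairwise-disjoint intervals, merging book-ended neighbours
(distance-0 merge, matching ``bedtools merge`` defaults), so every public
operation works on canonical input and total_bp arithmetic is exact.
"""

from __future__ import annotations

from typing import Dict, Iterable, Iterator, List, Mapping, Tuple

Interval = Tuple[int, int]


def _merge_sorted(pairs: List[Interval]) -> List[Interval]:
    """Merge a sorted list of (start, end) pairs; book-ended intervals fuse."""
    out: List[Interval] = []
    for s, e in pairs:
        if e <= s:
            if e < s:
                raise ValueError(f"negative-width interval [{s}, {e})")
            continue  # zero-width: contributes nothing
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


class RegionSet:
    """Per-chromosome sorted disjoint half-open intervals.

    Supports exact set algebra (union, intersection, difference,
    complement), membership and bp accounting. Instances are immutable
    in intent: mutate only via the operators, which return new sets.
    """

    __slots__ = ("_ivs",)

    def __init__(self, intervals: Mapping[str, Iterable[Interval]] | None = None):
        self._ivs: Dict[str, List[Interval]] = {}
        if intervals:
            for chrom, pairs in intervals.items():
                merged = _merge_sorted(sorted((int(s), int(e)) for s, e in pairs))
                if merged:
                    if merged[0][0] < 0:
                        raise ValueError(f"negative coordinate on {chrom}")
                    self._ivs[chrom] = merged

    # ---------------- construction ----------------

    @classmethod
    def from_pairs(cls, triples: Iterable[Tuple[str, int, int]]) -> "RegionSet":
        by_chrom: Dict[str, List[Interval]] = {}
        for chrom, s, e in triples:
            by_chrom.setdefault(chrom, []).append((s, e))
        return cls(by_chrom)

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        triples = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                triples.append((f[0], int(f[1]), int(f[2])))
        return cls.from_pairs(triples)

    @classmethod
    def whole_genome(cls, chrom_sizes: Mapping[str, int]) -> "RegionSet":
        return cls({c: [(0, n)] for c, n in chrom_sizes.items()})

    # ---------------- basics ----------------

    def chroms(self) -> List[str]:
        return sorted(self._ivs)

    def intervals(self, chrom: str) -> List[Interval]:
        return list(self._ivs.get(chrom, []))

    def __iter__(self) -> Iterator[Tuple[str, int, int]]:
        for chrom in sorted(self._ivs):
            for s, e in self._ivs[chrom]:
                yield chrom, s, e

    @property
    def total_bp(self) -> int:
        return sum(e - s for ivs in self._ivs.values() for s, e in ivs)

    def __bool__(self) -> bool:
        return bool(self._ivs)

    def __len__(self) -> int:
        return sum(len(v) for v in self._ivs.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self._ivs == other._ivs

    def __repr__(self) -> str:
        return f"RegionSet({len(self)} intervals, {self.total_bp} bp)"

    def contains(self, chrom: str, pos: int) -> bool:
        import bisect

        ivs = self._ivs.get(chrom)
        if not ivs:
            return False
        i = bisect.bisect_right(ivs, (pos, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= pos < ivs[i][1]

    # ---------------- algebra ----------------

    def union(self, other: "RegionSet") -> "RegionSet":
        out: Dict[str, List[Interval]] = {}
        for chrom in set(self._ivs) | set(other._ivs):
            out[chrom] = self._ivs.get(chrom, []) + other._ivs.get(chrom, [])
        return RegionSet(out)

    def intersection(self, other: "RegionSet") -> "RegionSet":
        out: Dict[str, List[Interval]] = {}
        for chrom in set(self._ivs) & set(other._ivs):
            a, b = self._ivs[chrom], other._ivs[chrom]
            i = j = 0
            acc: List[Interval] = []
            while i < len(a) and j < len(b):
                s = max(a[i][0], b[j][0])
                e = min(a[i][1], b[j][1])
                if s < e:
                    acc.append((s, e))
                if a[i][1] <= b[j][1]:
                    i += 1
                else:
                    j += 1
            if acc:
                out[chrom] = acc
        return RegionSet(out)

    def difference(self, other: "RegionSet") -> "RegionSet":
        out: Dict[str, List[Interval]] = {}
        for chrom, a in self._ivs.items():
            b = other._ivs.get(chrom, [])
            acc: List[Interval] = []
            j = 0
            for s, e in a:
                cur = s
                while j < len(b) and b[j][1] <= cur:
                    j += 1
                k = j
                while k < len(b) and b[k][0] < e:
                    if b[k][0] > cur:
                        acc.append((cur, b[k][0]))
                    cur = max(cur, b[k][1])
                    if cur >= e:
                        break
                    k += 1
                if cur < e:
                    acc.append((cur, e))
            if acc:
                out[chrom] = acc
        return RegionSet(out)

    def complement(self, chrom_sizes: Mapping[str, int]) -> "RegionSet":
        return RegionSet.whole_genome(chrom_sizes).difference(self)

    # ---------------- I/O ----------------

    def to_bed(self, path, label: str | None = None) -> None:
        with open(path, "w") as fh:
            for chrom, s, e in self:
                if label is None:
                    fh.write(f"{chrom}\t{s}\t{e}\n")
                else:
                    fh.write(f"{chrom}\t{s}\t{e}\t{label}\n")
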