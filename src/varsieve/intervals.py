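"""Per-genome interval sets (0-based, half-open), used for masks and
confident/ambiguous region bookkeeping.

Intervals are stored merged and sorted per contig.  Coordinates follow BED
conventions; conversion from 1-based VCF positions happens at the call sites.
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Dict, Iterable, Iterator, List, Mapping, Tuple


def _merge(ivs: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    for start, end in sorted(ivs):
        if out and start <= out[-1][1]:
            if end > out[-1][1]:
                out[-1] = (out[-1][0], end)
        else:
            out.append((start, end))
    return out


class GenomeIntervals:
    """A set of disjoint genomic intervals, one sorted list per contig."""

    def __init__(self, intervals: Iterable[Tuple[str, int, int]] = ()) -> None:
        raw: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start < 0 or end < start:
                raise ValueError(f"bad interval {chrom}:{start}-{end}")
            if end > start:
                raw.setdefault(chrom, []).append((start, end))
        self._by_chrom: Dict[str, List[Tuple[int, int]]] = {
            c: _merge(ivs) for c, ivs in raw.items()
        }

    # -- construction -------------------------------------------------

    @classmethod
    def from_bed(cls, path) -> "GenomeIntervals":
        ivs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                ivs.append((chrom, int(start), int(end)))
        return cls(ivs)

    def copy(self) -> "GenomeIntervals":
        new = GenomeIntervals()
        new._by_chrom = {c: list(ivs) for c, ivs in self._by_chrom.items()}
        return new

    # -- set algebra ---------------------------------------------------

    def union(self, other: "GenomeIntervals") -> "GenomeIntervals":
        return GenomeIntervals(list(self) + list(other))

    def add(self, chrom: str, start: int, end: int) -> "GenomeIntervals":
        """Return a new set with [start, end) on *chrom* added."""
        return GenomeIntervals(list(self) + [(chrom, start, end)])

    def complement(self, contig_lengths: Mapping[str, int]) -> "GenomeIntervals":
        """Complement over the given contigs (BEDtools-complement semantics)."""
        out = []
        for chrom, length in contig_lengths.items():
            prev = 0
            for start, end in self._by_chrom.get(chrom, []):
                if start > length:
                    break
                out.append((chrom, prev, min(start, length)))
                prev = min(end, length)
            out.append((chrom, prev, length))
        return GenomeIntervals(out)

    def intersect(self, other: "GenomeIntervals") -> "GenomeIntervals":
        out = []
        for chrom, ivs in self._by_chrom.items():
            for start, end in ivs:
                for s2, e2 in other._by_chrom.get(chrom, []):
                    s, e = max(start, s2), min(end, e2)
                    if e > s:
                        out.append((chrom, s, e))
        return GenomeIntervals(out)

    # -- queries -------------------------------------------------------

    def contains(self, chrom: str, pos0: int) -> bool:
        """True if the 0-based position lies inside the set."""
        return self.overlaps(chrom, pos0, pos0 + 1)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) intersects any stored interval."""
        ivs = self._by_chrom.get(chrom)
        if not ivs:
            return False
        i = bisect_right([s for s, _ in ivs], start)
        if i > 0 and ivs[i - 1][1] > start:
            return True
        return i < len(ivs) and ivs[i][0] < end

    def covers(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) lies entirely inside one stored interval."""
        ivs = self._by_chrom.get(chrom)
        if not ivs or end <= start:
            return False
        i = bisect_right([s for s, _ in ivs], start)
        return i > 0 and ivs[i - 1][1] >= end

    def total_length(self) -> int:
        return sum(e - s for _, s, e in self)

    @property
    def chroms(self) -> List[str]:
        return sorted(self._by_chrom)

    def is_empty(self) -> bool:
        return not any(self._by_chrom.values())

    def __iter__(self) -> Iterator[Tuple[str, int, int]]:
        for chrom in sorted(self._by_chrom):
            for start, end in self._by_chrom[chrom]:
                yield chrom, start, end

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeIntervals):
            return NotImplemented
        return {c: v for c, v in self._by_chrom.items() if v} == {
            c: v for c, v in other._by_chrom.items() if v
        }

    def __repr__(self) -> str:
        return f"GenomeIntervals({list(self)!r})"

    # -- I/O -----------------------------------------------------------

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self:
                fh.write(f"{chrom}\t{start}\t{end}\n")
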