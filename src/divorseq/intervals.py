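"""Genomic coordinate primitives.

Every coordinate in this package is 0-based, half-open ``[start, end)``.
One-based formats (wiggle fixedStep/variableStep) are converted at the I/O
boundary so that downstream base-offset arithmetic (the -8 bp cross-linking
position, the -37 bp roadblock window) is free of off-by-one drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded half-open interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """A called binding peak with an absolute summit coordinate.

    ``summit`` is the 0-based genomic position of the point of highest
    enrichment; narrowPeak files store it as an offset from ``start`` and
    readers convert it to an absolute coordinate.
    """

    interval: GenomicInterval
    summit: int
    fold_enrichment: float
    score: float = 0.0
    id: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"peak {self.id or '?'}: summit {self.summit} outside "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if self.fold_enrichment < 0:
            raise ValueError("fold_enrichment must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def interval_overlap(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """All index pairs ``(i, j)`` where ``a[i]`` and ``b[j]`` share >= 1 bp.

    Half-open semantics: adjacent intervals ([0,10) vs [10,20)) do not
    overlap. Sort-based sweep per chromosome, O((n+m) log(n+m) + k).
    """
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, iv in enumerate(b):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, j))
    for ivs in by_chrom.values():
        ivs.sort()

    import bisect

    pairs: list[tuple[int, int]] = []
    for i, iv in enumerate(a):
        cands = by_chrom.get(iv.chrom)
        if not cands:
            continue
        # candidates with start < iv.end; then filter end > iv.start
        hi = bisect.bisect_left(cands, (iv.end, -1, -1))
        for start, end, j in cands[:hi]:
            if end > iv.start:
                pairs.append((i, j))
    pairs.sort()
    return pairs


def points_in_intervals(
    points: Iterable[tuple[str, int]], intervals: Sequence[GenomicInterval]
) -> list[bool]:
    """For each (chrom, pos) point, whether it lies inside any interval."""
    import bisect

    import numpy as np

    by_chrom: dict[str, tuple[list[int], "np.ndarray"]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, ([], []))  # type: ignore[arg-type]
    tmp: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        tmp.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, ivs in tmp.items():
        ivs.sort()
        starts = [s for s, _ in ivs]
        # running max of ends lets one bisect answer "does any interval
        # starting at or before pos extend past pos?"
        ends = np.maximum.accumulate(np.array([e for _, e in ivs]))
        by_chrom[chrom] = (starts, ends)

    out = []
    for chrom, pos in points:
        entry = by_chrom.get(chrom)
        if entry is None:
            out.append(False)
            continue
        starts, max_ends = entry
        idx = bisect.bisect_right(starts, pos)
        out.append(idx > 0 and int(max_ends[idx - 1]) > pos)
    return out
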