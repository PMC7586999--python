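"""In-memory per-base coverage tracks and genome sequences."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from .intervals import GenomicInterval

_DNA = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class CoverageTrack:
    """Per-chromosome per-base nonnegative signal.

    Chromosome lengths are fixed at construction. ``total_signal`` is the
    sum of all per-base values and is recomputed, so it always agrees with
    the data to floating-point accuracy.
    """

    def __init__(self, chrom_sizes: Mapping[str, int]):
        if not chrom_sizes:
            raise ValueError("chrom_sizes must be nonempty")
        self._data: dict[str, np.ndarray] = {
            chrom: np.zeros(int(size), dtype=float)
            for chrom, size in chrom_sizes.items()
        }

    @classmethod
    def from_arrays(cls, arrays: Mapping[str, np.ndarray]) -> "CoverageTrack":
        track = cls({c: len(a) for c, a in arrays.items()})
        for chrom, arr in arrays.items():
            track._data[chrom] = np.asarray(arr, dtype=float).copy()
        return track

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self._data.items()}

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    @property
    def total_signal(self) -> float:
        return float(sum(a.sum() for a in self._data.values()))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._data

    def __getitem__(self, chrom: str) -> np.ndarray:
        try:
            return self._data[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in track") from None

    def add(self, chrom: str, start: int, end: int, value: float) -> None:
        """Add ``value`` to every base of ``[start, end)`` (clipped)."""
        arr = self[chrom]
        self._data[chrom][max(0, start) : min(len(arr), end)] += value

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Signal over ``[start, end)``; raises if outside the chromosome."""
        arr = self[chrom]
        if start < 0 or end > len(arr):
            raise ValueError(
                f"window {chrom}:{start}-{end} outside chromosome of length {len(arr)}"
            )
        return arr[start:end]

    def scaled(self, factor: float) -> "CoverageTrack":
        out = CoverageTrack(self.chrom_sizes)
        for chrom, arr in self._data.items():
            out._data[chrom] = arr * factor
        return out

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(self._data.items())


@dataclass
class StrandedCoverage:
    """A plus/minus pair of coverage tracks over the same chromosome set.

    Used for Pol II signal where strand identity matters: when a profile is
    reoriented to a minus-strand motif, the plus and minus sub-tracks swap.
    """

    plus: CoverageTrack
    minus: CoverageTrack

    def __post_init__(self) -> None:
        if self.plus.chrom_sizes != self.minus.chrom_sizes:
            raise ValueError("plus/minus tracks must share chromosome sizes")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return self.plus.chrom_sizes


class GenomeSequence:
    """Uppercase DNA sequences over {A, C, G, T, N}, one per chromosome."""

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("no sequences")
        self._seqs: dict[str, str] = {}
        for chrom, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - _DNA
            if bad:
                raise ValueError(f"{chrom}: non-DNA characters {sorted(bad)}")
            self._seqs[chrom] = seq

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        try:
            return self._seqs[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome") from None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``[start, end)``, padded with N beyond chromosome ends."""
        seq = self[chrom]
        left = "N" * max(0, -start)
        right = "N" * max(0, end - len(seq))
        return left + seq[max(0, start) : min(len(seq), end)] + right

    def base(self, chrom: str, pos: int) -> str:
        """Single base at ``pos``; N if off-chromosome."""
        seq = self[chrom]
        if 0 <= pos < len(seq):
            return seq[pos]
        return "N"

    def fetch_interval(self, iv: GenomicInterval) -> str:
        """Sequence of an interval, reverse-complemented for minus strand."""
        seq = self.fetch(iv.chrom, iv.start, iv.end)
        return revcomp(seq) if iv.strand == "-" else seq
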