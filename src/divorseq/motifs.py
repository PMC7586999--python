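"""Position-weight-matrix construction and strand-aware scanning.

Scoring is additive over scaled base frequencies (no log-odds, no
background model): a PFM's columns are normalized to frequencies,
multiplied by a scale factor (default 1000) and used directly as column
scores. A window's score fraction is its score over the best attainable
score, and matches are reported when that fraction reaches a threshold
(default 85%). Minus-strand windows are scored on the reverse complement.

The motif *midpoint* of a length-L motif is position ``L // 2`` in motif
orientation (0-based); for an even L this is the base just 3' of centre.
The cross-linkability base sits 8 bp 5' of the midpoint on the motif
strand ("-8 bp"); an N there fails the G/C test since cross-linkability
cannot be asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .tracks import GenomeSequence, revcomp

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


@dataclass(frozen=True)
class PWM:
    """4 x L additive score matrix, rows A, C, G, T."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != 4 or w.shape[1] < 1:
            raise ValueError("PWM weights must be a 4 x L matrix with L >= 1")
        object.__setattr__(self, "weights", w)

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=0).sum())

    @property
    def midpoint_index(self) -> int:
        return self.length // 2

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.weights.argmax(axis=0))

    def score(self, window: str) -> float:
        """Additive score of one window (len == L); N scores the column
        minimum."""
        if len(window) != self.length:
            raise ValueError("window length must equal motif length")
        total = 0.0
        for i, base in enumerate(window.upper()):
            col = self.weights[:, i]
            idx = _BASE_INDEX.get(base)
            total += col[idx] if idx is not None else col.min()
        return float(total)


@dataclass(frozen=True)
class MotifMatch:
    """One PWM match. ``midpoint`` is the absolute 0-based genomic position
    of the motif midpoint; ``minus8_base`` is the base 8 bp 5' of it in
    motif orientation (complemented for minus-strand matches)."""

    chrom: str
    midpoint: int
    strand: str
    score: float
    score_frac: float
    minus8_base: str = "N"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("match strand must be + or -")
        if self.score_frac > 1 + 1e-9:
            raise ValueError("score_frac cannot exceed 1")


def pfm_to_pwm(pfm: np.ndarray, scale: float = 1000.0) -> PWM:
    """Convert a position frequency matrix (counts or frequencies) to an
    additive PWM: columns normalized to frequencies, then multiplied by
    ``scale``."""
    pfm = np.asarray(pfm, dtype=float)
    if pfm.ndim != 2 or pfm.shape[0] != 4:
        raise ValueError("PFM must be 4 x L (rows A, C, G, T)")
    if (pfm < 0).any():
        raise ValueError("PFM entries must be nonnegative")
    colsums = pfm.sum(axis=0)
    if (colsums == 0).any():
        raise ValueError("PFM has an all-zero column")
    return PWM(weights=pfm / colsums * scale)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    idx = np.full(arr.shape, -1, dtype=np.int64)
    for base, i in _BASE_INDEX.items():
        idx[arr == ord(base)] = i
    return idx


def _window_scores(idx: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Score of every window start on the encoded forward sequence."""
    L = weights.shape[1]
    n_windows = len(idx) - L + 1
    scores = np.zeros(n_windows)
    col_min = weights.min(axis=0)
    for i in range(L):
        col = weights[:, i]
        sub = idx[i : i + n_windows]
        scores += np.where(sub >= 0, col[np.clip(sub, 0, 3)], col_min[i])
    return scores


def scan_pwm(
    seq: str,
    pwm: PWM,
    min_score_frac: float = 0.85,
    both_strands: bool = True,
    chrom: str = "",
    offset: int = 0,
) -> list[MotifMatch]:
    """Report every window on (both strands of) ``seq`` scoring at least
    ``min_score_frac * pwm.max_score``.

    ``offset`` is the absolute genomic coordinate of ``seq[0]`` so match
    midpoints are reported in genome coordinates. The minus-strand
    midpoint is the genomic base carrying motif position L//2 of the
    reverse-complement match. ``minus8_base`` is filled from ``seq`` when
    the -8 position falls inside it, else N (use :func:`annotate_minus8`).
    """
    L = pwm.length
    if len(seq) < L:
        return []
    idx = _encode(seq)
    threshold = min_score_frac * pwm.max_score
    mid = pwm.midpoint_index
    matches: list[MotifMatch] = []

    fwd = _window_scores(idx, pwm.weights)
    for s in np.flatnonzero(fwd >= threshold):
        midpoint = offset + int(s) + mid
        matches.append(
            MotifMatch(
                chrom=chrom,
                midpoint=midpoint,
                strand="+",
                score=float(fwd[s]),
                score_frac=float(fwd[s]) / pwm.max_score,
                minus8_base=_base_at(seq, int(s) + mid - 8),
            )
        )
    if both_strands:
        rc_idx = _encode(revcomp(seq))
        rev = _window_scores(rc_idx, pwm.weights)
        n = len(seq)
        for s_rc in np.flatnonzero(rev >= threshold):
            # window start on the forward strand, motif read 3'->5' there
            s = n - L - int(s_rc)
            midpoint = offset + s + (L - 1 - mid)
            matches.append(
                MotifMatch(
                    chrom=chrom,
                    midpoint=midpoint,
                    strand="-",
                    score=float(rev[s_rc]),
                    score_frac=float(rev[s_rc]) / pwm.max_score,
                    minus8_base=_rc_base_at(seq, s + (L - 1 - mid) + 8),
                )
            )
    matches.sort(key=lambda m: (m.midpoint, m.strand))
    return matches


def _base_at(seq: str, pos: int) -> str:
    if 0 <= pos < len(seq):
        base = seq[pos].upper()
        return base if base in _BASES else "N"
    return "N"


def _rc_base_at(seq: str, pos: int) -> str:
    return revcomp(_base_at(seq, pos))


def annotate_minus8(match: MotifMatch, genome: GenomeSequence) -> MotifMatch:
    """Fill ``minus8_base`` from the genome: 8 bp 5' of the midpoint on the
    motif strand (genomic midpoint - 8 for +, midpoint + 8 complemented
    for -)."""
    if match.strand == "+":
        base = genome.base(match.chrom, match.midpoint - 8)
    else:
        base = revcomp(genome.base(match.chrom, match.midpoint + 8))
    return replace(match, minus8_base=base if base in _BASES else "N")


def best_match(
    matches: Sequence[MotifMatch], summit: int | None = None
) -> MotifMatch:
    """The highest-scoring match; ties broken by distance to the peak
    summit (when given), then by + strand."""
    if not matches:
        raise ValueError("best_match of an empty match list")

    def key(m: MotifMatch):
        dist = abs(m.midpoint - summit) if summit is not None else 0
        return (-m.score, dist, 0 if m.strand == "+" else 1)

    return min(matches, key=key)


def oriented_context(
    genome: GenomeSequence, match: MotifMatch, flank_up: int, flank_down: int
) -> str:
    """Sequence around the motif midpoint in motif orientation, covering
    offsets [-flank_up, +flank_down] (so -8 and -1 contexts are included
    when flank_up >= 8)."""
    g = match.midpoint
    if match.strand == "+":
        return genome.fetch(match.chrom, g - flank_up, g + flank_down + 1)
    return revcomp(genome.fetch(match.chrom, g - flank_down, g + flank_up + 1))


def consensus_counts(
    best_matches: Sequence[MotifMatch],
    genome: GenomeSequence,
    flank_up: int = 10,
    flank_down: int = 10,
) -> pd.DataFrame:
    """Per-position base counts over motif-oriented windows around each
    site's best match: rows A, C, G, T; columns are offsets from the motif
    midpoint (negative = 5' in motif orientation). Suitable for rendering
    sequence logos per residence-time quartile."""
    offsets = list(range(-flank_up, flank_down + 1))
    counts = pd.DataFrame(0, index=list(_BASES), columns=offsets)
    for m in best_matches:
        ctx = oriented_context(genome, m, flank_up, flank_down)
        for off, base in zip(offsets, ctx):
            if base in _BASES:
                counts.loc[base, off] += 1
    return counts


def position_enrichment_test(
    group_counts: Sequence[float], rest_counts: Sequence[float], base: str
) -> float:
    """Two-sided Fisher exact test for enrichment of ``base`` at one motif
    position in a group of sites versus the rest.

    Counts are length-4 vectors in A, C, G, T order. The choice of
    Fisher's exact test is this package's default for small base-count
    tables; other tests would be defensible.
    """
    from scipy import stats

    gi = _BASE_INDEX[base.upper()]
    g = np.asarray(group_counts, dtype=float)
    r = np.asarray(rest_counts, dtype=float)
    table = np.array(
        [[g[gi], g.sum() - g[gi]], [r[gi], r.sum() - r[gi]]]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("position_enrichment_test: a table margin is zero")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
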