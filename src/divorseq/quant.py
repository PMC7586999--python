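"""Fragment evidence -> comparable per-site binding values.

The quantification chain for each sample of the depletion time course:

1. midpoint coverage — each paired-end fragment contributes a boxcar of
   weight 1 centred on its midpoint (default 101 bp), so coverage at a base
   counts fragment midpoints within +/- 50 bp;
2. depth scaling to a common fragment count (default 1e6), equalizing total
   genome coverage across samples;
3. window quantification — summed coverage over summit +/- 50 bp;
4. background normalization — divide by the sample's background read
   fraction (reads whose midpoints fall outside every called peak), which
   equalizes background levels between time points;
5. replicate-outlier flagging by a cross-replicate MAD rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, Peak, points_in_intervals
from .tracks import CoverageTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class SampleLabel:
    """Identity of one sequencing sample: minutes since depletion induction
    (0 = mock), biological replicate number, and IP vs input role."""

    time_min: float
    replicate: int
    role: str = "IP"

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValueError("time_min must be >= 0")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.role not in ("IP", "input"):
            raise ValueError("role must be 'IP' or 'input'")

    def __str__(self) -> str:
        return f"t{self.time_min:g}_rep{self.replicate}_{self.role}"


@dataclass
class QuantifiedSample:
    """Per-peak window sums for one sample, before and after background
    normalization. normalized = raw / background_fraction, peak-wise."""

    label: SampleLabel
    raw: np.ndarray
    background_fraction: float
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not (0 < self.background_fraction <= 1):
            raise ValueError("background_fraction must be in (0, 1]")
        self.raw = np.asarray(self.raw, dtype=float)
        self.normalized = self.raw / self.background_fraction


def build_midpoint_coverage(
    fragments: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    window_bp: int = 101,
) -> CoverageTrack:
    """Midpoint-and-smooth coverage: each fragment adds 1.0 over the
    ``window_bp`` bases centred on its midpoint, truncated at chromosome
    ends."""
    if window_bp % 2 == 0 or window_bp < 1:
        raise ValueError(f"window_bp must be a positive odd integer, got {window_bp}")
    half = (window_bp - 1) // 2
    track = CoverageTrack(chrom_sizes)
    for frag in fragments:
        mid = frag.midpoint
        track.add(frag.chrom, mid - half, mid + half + 1, 1.0)
    return track


def scale_track(
    track: CoverageTrack,
    actual_fragments: int,
    target_fragments: float = 1e6,
) -> CoverageTrack:
    """Scale every base by target/actual fragment counts so total genome
    coverage is equal across samples."""
    if actual_fragments <= 0:
        raise ValueError("actual_fragments must be > 0")
    return track.scaled(target_fragments / actual_fragments)


def quantify_peak(track: CoverageTrack, chrom: str, summit: int, half_width: int = 50) -> float:
    """Summed signal over the closed window summit +/- half_width
    (2*half_width + 1 bases), clipped at chromosome ends."""
    if chrom not in track:
        raise ValueError(f"summit chromosome {chrom!r} not in track")
    arr = track[chrom]
    if not (0 <= summit < len(arr)):
        raise ValueError(f"summit {summit} outside chromosome {chrom}")
    return float(arr[max(0, summit - half_width) : summit + half_width + 1].sum())


def quantify_peaks(
    track: CoverageTrack, peaks: Sequence[Peak], half_width: int = 50
) -> np.ndarray:
    return np.array(
        [quantify_peak(track, p.chrom, p.summit, half_width) for p in peaks]
    )


def background_fraction(
    fragments: Sequence[GenomicInterval], peaks: Sequence[Peak]
) -> float:
    """Fraction of fragments whose midpoint lies outside every peak
    interval. Computed against the full unfiltered peak set."""
    if not fragments:
        raise ValueError("no fragments")
    inside = points_in_intervals(
        ((f.chrom, f.midpoint) for f in fragments), [p.interval for p in peaks]
    )
    return 1.0 - sum(inside) / len(fragments)


def background_normalize(
    label: SampleLabel,
    raw_values: np.ndarray,
    total_reads: int,
    reads_in_peaks: int,
) -> QuantifiedSample:
    """Divide per-peak sums by the sample's background read fraction
    (total - in-peak) / total. Ratios between peaks are preserved exactly."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if reads_in_peaks > total_reads:
        raise ValueError("reads_in_peaks cannot exceed total_reads")
    frac = (total_reads - reads_in_peaks) / total_reads
    if frac == 0:
        raise ValueError(
            f"sample {label}: all reads fall inside peaks; background "
            "normalization undefined"
        )
    return QuantifiedSample(label=label, raw=raw_values, background_fraction=frac)


def flag_outlier_samples(
    quantified: Mapping[SampleLabel, np.ndarray],
    fold_threshold: float = 6.0,
) -> list[SampleLabel]:
    """Flag replicates that deviate grossly from the other replicates at
    the same time point.

    For each sample, the median absolute deviation (MAD) of its per-peak
    values around the per-peak cross-replicate median at its time point is
    compared to the median MAD of the other replicates there; a sample is
    flagged when its MAD is strictly more than ``fold_threshold`` times as
    high. Time points with a single replicate are skipped with a warning.
    """
    by_time: dict[float, list[SampleLabel]] = {}
    for label in quantified:
        by_time.setdefault(label.time_min, []).append(label)

    flagged: list[SampleLabel] = []
    for time_min, labels in sorted(by_time.items()):
        if len(labels) < 2:
            logger.warning(
                "time point %g min has a single replicate; outlier check skipped",
                time_min,
            )
            continue
        values = np.stack([np.asarray(quantified[lab], dtype=float) for lab in labels])
        per_peak_median = np.median(values, axis=0)
        mads = np.median(np.abs(values - per_peak_median), axis=1)
        for i, label in enumerate(labels):
            others = np.delete(mads, i)
            ref = float(np.median(others))
            if mads[i] > fold_threshold * ref:
                flagged.append(label)
                logger.info(
                    "flagged %s: MAD %.4g vs replicate median %.4g",
                    label, mads[i], ref,
                )
    return flagged
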