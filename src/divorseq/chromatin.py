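"""Residence-time-stratified chromatin and transcription metrics.

All metrics share one offset convention: profiles are anchored on the best
motif match of each site and expressed in *motif orientation* — negative
offsets are 5' of the motif midpoint on the motif strand. Minus-strand
anchors therefore have their signal windows reversed, and for stranded
(Pol II) tracks the plus and minus sub-tracks are additionally swapped
before reversal, so "sense" always means the strand the motif points
along.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig
from scipy import stats

from .tracks import CoverageTrack, StrandedCoverage

logger = logging.getLogger(__name__)


class Anchor(NamedTuple):
    """A motif-midpoint anchor: chromosome, 0-based position, strand."""

    chrom: str
    midpoint: int
    strand: str


@dataclass
class MetaProfile:
    """Mean +/- SEM signal per offset around a set of anchors."""

    offsets: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_sites: int

    def __post_init__(self) -> None:
        if not (len(self.offsets) == len(self.mean) == len(self.sem)):
            raise ValueError("offsets, mean and sem must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean": self.mean, "sem": self.sem,
             "n": self.n_sites}
        )


def moving_average(values: np.ndarray, window_bp: int) -> np.ndarray:
    """Centred moving average with edge windows shrunk to the data."""
    if window_bp % 2 == 0 or window_bp < 1:
        raise ValueError("smoothing window must be a positive odd integer")
    if window_bp == 1:
        return np.asarray(values, dtype=float)
    kernel = np.ones(window_bp)
    v = np.asarray(values, dtype=float)
    return np.convolve(v, kernel, mode="same") / np.convolve(
        np.ones_like(v), kernel, mode="same"
    )


def extract_site_signal(
    track: CoverageTrack | StrandedCoverage,
    anchor: Anchor,
    flank: int,
) -> np.ndarray:
    """Per-base signal over anchor +/- flank in motif orientation.

    For a plain track, minus-strand anchors get the window reversed. For a
    stranded pair, the *sense* sub-track is used: plus track for + anchors,
    minus track (then reversed) for - anchors — the strand swap of the
    reorientation.
    """
    if anchor.strand not in ("+", "-"):
        raise ValueError("anchor strand must be + or -")
    if isinstance(track, StrandedCoverage):
        base = track.plus if anchor.strand == "+" else track.minus
    else:
        base = track
    window = base.window(anchor.chrom, anchor.midpoint - flank, anchor.midpoint + flank + 1)
    window = np.asarray(window, dtype=float).copy()
    return window[::-1] if anchor.strand == "-" else window


def aggregate_profile(
    track: CoverageTrack | StrandedCoverage,
    anchors: Sequence[Anchor],
    flank: int,
    smooth_bp: int | None = None,
) -> MetaProfile:
    """Average motif-oriented signal across anchors.

    Anchors whose window exceeds the chromosome bounds are dropped with a
    warning. SEM is the per-offset standard error across sites (0 when a
    single site remains). Optional centred moving-average smoothing is
    applied to the mean (matching the plotting convention of smoothing the
    aggregate, e.g. 3 bp for nuclease cut profiles).
    """
    if not anchors:
        raise ValueError("aggregate_profile needs at least one anchor")
    rows = []
    for anchor in anchors:
        try:
            rows.append(extract_site_signal(track, anchor, flank))
        except ValueError:
            logger.warning("anchor %s dropped: window exceeds chromosome", (anchor,))
    if not rows:
        raise ValueError("no anchor fits within the chromosome bounds")
    data = np.stack(rows)
    mean = data.mean(axis=0)
    sem = (
        data.std(axis=0, ddof=1) / np.sqrt(len(rows))
        if len(rows) > 1
        else np.zeros_like(mean)
    )
    if smooth_bp is not None:
        mean = moving_average(mean, smooth_bp)
        sem = moving_average(sem, smooth_bp)
    offsets = np.arange(-flank, flank + 1)
    return MetaProfile(offsets=offsets, mean=mean, sem=sem, n_sites=len(rows))


def mnase_protection_ratio(
    cuts_before: CoverageTrack,
    cuts_after: CoverageTrack,
    anchor: Anchor,
    inner: int = 8,
) -> float | None:
    """Nuclease protection by the bound factor at one site.

    Ratio of mean per-base cut density over the motif footprint
    [midpoint - inner, midpoint + inner] (17 bases by default) after
    depletion over before. A ratio > 1 means the factor was shielding the
    footprint. Sites with zero cuts in either condition are excluded
    (returns None).
    """
    before = extract_site_signal(cuts_before, anchor, inner)
    after = extract_site_signal(cuts_after, anchor, inner)
    if before.sum() == 0 or after.sum() == 0:
        return None
    return float(after.mean() / before.mean())


def nfr_width(
    occupancy: MetaProfile | np.ndarray,
    smooth_bp: int = 31,
    min_offset: int = 30,
    prominence_frac: float = 0.10,
    dyads: tuple[int, int] | None = None,
) -> int:
    """Distance in bp between the -1 and +1 nucleosome midpoints flanking
    the anchor.

    When ``dyads`` (externally annotated -1/+1 dyad offsets) is given it
    takes precedence. Otherwise the occupancy profile is smoothed with a
    centred moving average (default 31 bp) and the -1 (+1) nucleosome is
    the local maximum nearest the anchor at offset < -min_offset
    (> +min_offset) with prominence at least ``prominence_frac`` of the
    profile maximum.
    """
    if dyads is not None:
        up, down = dyads
        if not (up < 0 < down):
            raise ValueError("dyad offsets must bracket the anchor (up < 0 < down)")
        return int(down - up)

    if isinstance(occupancy, MetaProfile):
        values = occupancy.mean
        offsets = occupancy.offsets
    else:
        values = np.asarray(occupancy, dtype=float)
        if len(values) % 2 == 0:
            raise ValueError("occupancy vector must be centred (odd length)")
        flank = (len(values) - 1) // 2
        offsets = np.arange(-flank, flank + 1)
    if offsets[0] > -400 or offsets[-1] < 400:
        raise ValueError("occupancy must cover at least +/- 400 bp")
    if (values < 0).any():
        raise ValueError("occupancy must be nonnegative")

    smoothed = moving_average(values, smooth_bp)
    peaks, _ = _sig.find_peaks(smoothed, prominence=prominence_frac * smoothed.max())
    peak_offsets = offsets[peaks]
    upstream = peak_offsets[peak_offsets < -min_offset]
    downstream = peak_offsets[peak_offsets > min_offset]
    if len(upstream) == 0 or len(downstream) == 0:
        raise ValueError("no flanking nucleosome on one side of the anchor")
    minus1 = int(upstream.max())   # nearest qualifying maximum upstream
    plus1 = int(downstream.min())  # nearest qualifying maximum downstream
    return plus1 - minus1


@dataclass
class RoadblockResult:
    index: float | None
    is_roadblock: bool | None
    reason: str | None = None


def roadblock_index(
    polII: StrandedCoverage,
    anchor: Anchor,
    peak_window: tuple[int, int] = (-42, -32),
    upstream_window: tuple[int, int] = (-300, -100),
    threshold: float = 2.0,
) -> RoadblockResult:
    """Stalled-polymerase index at one site.

    Mean sense-strand Pol II signal in the roadblock window (default the
    closed 11-base window [-42, -32], i.e. -37 +/- 5 bp from the motif
    midpoint) divided by the mean over the incoming-transcription window
    (default [-300, -100]). Offsets are motif-oriented (sense strand after
    the strand swap). A site is a roadblock when the index is strictly
    greater than ``threshold``. Zero upstream signal makes the index
    undefined and the site is excluded with a reason.
    """
    flank = max(abs(v) for w in (peak_window, upstream_window) for v in w)
    sense = extract_site_signal(polII, anchor, flank)
    offsets = np.arange(-flank, flank + 1)

    def window_mean(lo: int, hi: int) -> float:
        mask = (offsets >= lo) & (offsets <= hi)
        return float(sense[mask].mean())

    upstream = window_mean(*upstream_window)
    if upstream <= 0:
        return RoadblockResult(None, None, "zero upstream Pol II signal")
    index = window_mean(*peak_window) / upstream
    return RoadblockResult(index=index, is_roadblock=bool(index > threshold))


@dataclass
class GroupComparison:
    """Result of a between-quartile test: the omnibus statistic and
    p-value, plus adjusted pairwise contrasts for Tukey's HSD."""

    test: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None


def group_compare(
    values: Sequence[float],
    groups: Sequence[str],
    test: str = "anova_tukey",
) -> GroupComparison:
    """Compare a per-site metric between groups (typically residence-time
    quartiles).

    ``anova_tukey``: one-way ANOVA with Tukey honest-significant-difference
    adjusted pairwise contrasts. ``ttest``: two-tailed two-sample t-test
    (exactly two groups). ``wilcoxon``: Wilcoxon rank-sum (Mann-Whitney U,
    exact for small tie-free samples).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = [str(g) for g in pd.unique(groups)]
    samples = {name: values[groups == name] for name in names}
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    if test in ("anova_tukey", "ttest"):
        for name, vals in samples.items():
            if len(vals) < 2:
                raise ValueError(f"group {name!r} has fewer than 2 values")

    if test == "anova_tukey":
        f_stat, p = stats.f_oneway(*samples.values())
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        tukey = pairwise_tukeyhsd(values, groups)
        pairwise = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        return GroupComparison("anova_tukey", float(f_stat), float(p), pairwise)
    if test == "ttest":
        if len(names) != 2:
            raise ValueError("ttest requires exactly 2 groups")
        t_stat, p = stats.ttest_ind(*samples.values())
        return GroupComparison("ttest", float(t_stat), float(p))
    if test == "wilcoxon":
        if len(names) != 2:
            raise ValueError("wilcoxon requires exactly 2 groups")
        a, b = samples.values()
        method = "exact" if (len(a) <= 25 and len(b) <= 25) else "auto"
        u_stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return GroupComparison("wilcoxon", float(u_stat), float(p))
    raise ValueError(f"unknown test {test!r}")
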