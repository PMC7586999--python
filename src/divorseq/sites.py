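"""Filter a called peak set down to the analyzable binding-site list.

Filters, in bookkeeping order (membership of the final set is
order-independent because each filter is a pure predicate on the peak):

1. fold enrichment >= fe_min (default 4) — initial binding must be strong
   enough to measure its decay;
2. at least one PWM match with score >= min_score_frac (default 85%) of
   the best attainable score, with the motif midpoint within
   summit +/- motif_flank (default 100 bp);
3. EVERY match at the peak must carry a G or C at -8 bp from the motif
   midpoint (efficient formaldehyde cross-linking); an A, T or N at -8 in
   any match drops the peak;
4. summit not inside a user-supplied telomeric interval (telomeric sites
   behave atypically and are excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .intervals import GenomicInterval, Peak, points_in_intervals
from .motifs import PWM, MotifMatch, best_match, scan_pwm
from .tracks import GenomeSequence

FILTER_ORDER = ("fold_enrichment", "motif", "minus8_gc", "telomere")


@dataclass
class BindingSite:
    """A peak together with its motif matches and filter outcome."""

    peak: Peak
    motif_matches: list[MotifMatch] = field(default_factory=list)
    passed_filters: set[str] = field(default_factory=set)
    excluded_reason: str | None = None
    quartile: str | None = None

    @property
    def id(self) -> str:
        return self.peak.id

    @property
    def best(self) -> MotifMatch:
        return best_match(self.motif_matches, summit=self.peak.summit)

    @property
    def passed(self) -> bool:
        return self.excluded_reason is None


@dataclass
class FilterResult:
    """Outcome of the filter cascade: the retained sites, dropped sites
    with their first failing filter, and the cascade survivor counts in
    filter order (n_input, after FE, after motif, after -8, after
    telomere)."""

    sites: list[BindingSite]
    dropped: list[BindingSite]
    cascade: list[int]

    @property
    def drop_counts(self) -> dict[str, int]:
        counts = {name: 0 for name in FILTER_ORDER}
        for site in self.dropped:
            counts[site.excluded_reason] += 1  # type: ignore[index]
        return counts


def filter_sites(
    peaks: Sequence[Peak],
    genome: GenomeSequence,
    pwm: PWM,
    fe_min: float = 4.0,
    motif_flank: int = 100,
    min_score_frac: float = 0.85,
    telomeres: Sequence[GenomicInterval] = (),
) -> FilterResult:
    """Apply the full filter cascade to ``peaks``.

    The motif scan covers summit +/- (motif_flank + motif length) so that
    any motif whose *midpoint* lies within summit +/- motif_flank is found;
    matches with midpoints outside that bound are discarded.
    """
    for p in peaks:
        if p.chrom not in genome:
            raise ValueError(f"peak {p.id}: chromosome {p.chrom!r} not in genome")

    telomeric = points_in_intervals(
        ((p.chrom, p.summit) for p in peaks), list(telomeres)
    )

    n = len(peaks)
    sites: list[BindingSite] = []
    dropped: list[BindingSite] = []
    predicates: list[dict[str, bool]] = []
    for p, is_telo in zip(peaks, telomeric):
        matches = _peak_matches(p, genome, pwm, motif_flank, min_score_frac)
        pred = {
            "fold_enrichment": p.fold_enrichment >= fe_min,
            "motif": bool(matches),
            "minus8_gc": bool(matches)
            and all(m.minus8_base in ("G", "C") for m in matches),
            "telomere": not is_telo,
        }
        predicates.append(pred)
        failures = [name for name in FILTER_ORDER if not pred[name]]
        site = BindingSite(
            peak=p,
            motif_matches=matches,
            passed_filters={name for name in FILTER_ORDER if pred[name]},
        )
        if failures:
            # drop charged to the first failing filter in cascade order
            site.excluded_reason = failures[0]
            dropped.append(site)
        else:
            sites.append(site)

    # survivor counts after filters 1..k applied cumulatively in order
    cascade = [n]
    alive = [True] * n
    for name in FILTER_ORDER:
        alive = [a and pred[name] for a, pred in zip(alive, predicates)]
        cascade.append(sum(alive))

    return FilterResult(sites=sites, dropped=dropped, cascade=cascade)


def _peak_matches(
    peak: Peak,
    genome: GenomeSequence,
    pwm: PWM,
    motif_flank: int,
    min_score_frac: float,
) -> list[MotifMatch]:
    L = pwm.length
    chrom_len = len(genome[peak.chrom])
    start = max(0, peak.summit - motif_flank - L)
    end = min(chrom_len, peak.summit + motif_flank + L + 1)
    seq = genome.fetch(peak.chrom, start, end)
    matches = scan_pwm(
        seq, pwm, min_score_frac=min_score_frac, chrom=peak.chrom, offset=start
    )
    # the +/- motif_flank bound applies to the motif midpoint
    kept = [m for m in matches if abs(m.midpoint - peak.summit) <= motif_flank]
    # minus8 from the full genome (scan may sit at a window edge)
    from .motifs import annotate_minus8

    return [annotate_minus8(m, genome) for m in kept]
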