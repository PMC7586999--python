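"""Synthetic depletion experiments with known ground truth.

Everything the pipeline consumes can be generated here: a genome with
planted motifs, per-sample fragment lists whose per-site counts decay with
known off-rates, a narrowPeak table, auxiliary chromatin tracks with
planted nucleosome-free-region geometry, protection depths and roadblock
indices, and a nascent-RNA count matrix. Defaults mirror the study
conditions: off-rates uniform on 0.03-0.24 1/min, 11 time points over 90
minutes, three biological replicates, Poisson counting noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as dio
from .chromatin import Anchor
from .decay import DEFAULT_TIME_GRID, TimeCourse, decay_model
from .intervals import GenomicInterval, Peak
from .motifs import PWM, pfm_to_pwm, scan_pwm
from .quant import SampleLabel
from .tracks import CoverageTrack, GenomeSequence, StrandedCoverage, revcomp

DEFAULT_KOFF_RANGE = (0.03, 0.24)

#: Failure-mode composition of the default filter-cascade fixture:
#: 7 clean sites plus planted failures of each filter.
DEFAULT_COMPOSITION = {
    "clean": 7,
    "low_fe": 5,
    "no_motif": 4,
    "at_minus8": 3,
    "telomeric": 1,
}


def default_pfm() -> np.ndarray:
    """A 13-bp general-regulatory-factor-style position frequency matrix:
    ten informative positions around a 3-bp degenerate spacer, rows
    A, C, G, T (counts summing to 100 per column)."""
    consensus = "ATCACTANNNACG"
    strong, weak = 91, 3
    cols = []
    for base in consensus:
        if base == "N":
            cols.append([25, 25, 25, 25])
        else:
            col = [weak] * 4
            col["ACGT".index(base)] = strong
            cols.append(col)
    return np.array(cols, dtype=float).T


@dataclass
class NoiseModel:
    """Observation noise for simulated binding values.

    ``poisson``: counts drawn Poisson around the model expectation (the
    natural model for fragment counting). ``lognormal``: multiplicative
    log-normal noise with coefficient of variation ~ ``sd``. ``none``:
    exact model values. ``replicate_effect_sd`` adds a per-replicate
    multiplicative log-normal offset shared across time points.
    """

    kind: str = "poisson"
    sd: float = 0.1
    replicate_effect_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("poisson", "lognormal", "none"):
            raise ValueError("noise kind must be poisson, lognormal or none")


@dataclass
class SiteTruth:
    """Ground truth for one simulated binding site."""

    site_id: str
    chrom: str
    summit: int
    motif_seq: str
    motif_strand: str
    koff_true: float
    y0_true: float
    yf_true: float
    minus8_base: str
    fold_enrichment_true: float
    telomeric: bool
    category: str

    def __post_init__(self) -> None:
        if self.koff_true <= 0:
            raise ValueError("koff_true must be > 0")
        if not (self.y0_true > self.yf_true >= 0):
            raise ValueError("require y0_true > yf_true >= 0")

    @property
    def passes_filters(self) -> bool:
        return self.category in ("clean",)


def simulate_timecourse(
    site_id: str,
    koff: float,
    y0: float,
    yf: float,
    times: Sequence[float] = DEFAULT_TIME_GRID,
    n_reps: int = 3,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> TimeCourse:
    """Sample a (replicate x time) matrix from the decay model under the
    given noise model. Deterministic given the noise seed (or ``rng``)."""
    noise = noise or NoiseModel()
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    times = np.asarray(times, dtype=float)
    if times[0] != 0:
        raise ValueError("times must include t = 0 first")
    expectation = decay_model(times, y0, yf, koff)
    rep_effects = (
        rng.lognormal(0.0, noise.replicate_effect_sd, size=n_reps)
        if noise.replicate_effect_sd > 0
        else np.ones(n_reps)
    )
    values = np.empty((n_reps, len(times)))
    for r in range(n_reps):
        mean = expectation * rep_effects[r]
        if noise.kind == "poisson":
            values[r] = rng.poisson(mean)
        elif noise.kind == "lognormal":
            if noise.sd > 0:
                sigma = np.sqrt(np.log1p(noise.sd**2))
                # mean-preserving multiplicative noise
                values[r] = mean * rng.lognormal(-sigma**2 / 2, sigma, size=len(times))
            else:
                values[r] = mean
        else:
            values[r] = mean
    return TimeCourse(site_id=site_id, times=times, values=values)


@dataclass
class SimulatedExperiment:
    """Bundle of everything a depletion ChIP time course comprises."""

    genome: GenomeSequence
    peaks: list[Peak]
    fragments: dict[SampleLabel, list[GenomicInterval]]
    truth: pd.DataFrame
    telomeres: list[GenomicInterval]
    pfm: np.ndarray
    times: tuple[float, ...]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return self.genome.chrom_sizes

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dio.write_fasta(self.genome, out / "genome.fa")
        dio.write_peaks(self.peaks, out / "peaks.narrowPeak")
        dio.write_pfm(self.pfm, out / "motif.pfm.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        with open(out / "genome.chrom.sizes", "w") as fh:
            for chrom, size in self.chrom_sizes.items():
                fh.write(f"{chrom}\t{size}\n")
        dio.write_fragments(self.telomeres, out / "telomeres.bed")
        rows = []
        for label, frags in self.fragments.items():
            name = f"fragments_{label}.bed"
            dio.write_fragments(frags, out / name)
            rows.append(
                {
                    "path": name,
                    "time_min": label.time_min,
                    "replicate": label.replicate,
                    "role": label.role,
                    "total_fragments": len(frags),
                }
            )
        pd.DataFrame(rows).to_csv(out / "samples.tsv", sep="\t", index=False)


def _random_genome(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_chip_experiment(
    composition: Mapping[str, int] | None = None,
    genome_length: int = 200_000,
    koff_range: tuple[float, float] = DEFAULT_KOFF_RANGE,
    pfm: np.ndarray | None = None,
    background_rate: float = 0.3,
    times: Sequence[float] = DEFAULT_TIME_GRID,
    n_reps: int = 3,
    noise: NoiseModel | None = None,
    seed: int = 0,
    telomere_bp: int = 5000,
    min_spacing: int = 2000,
) -> SimulatedExperiment:
    """Simulate a full depletion ChIP-seq time course on one synthetic
    chromosome.

    Sites are planted with known off-rates (uniform on ``koff_range``),
    plateau backgrounds and motif context; ``composition`` controls how
    many sites are constructed to fail each peak filter (see
    DEFAULT_COMPOSITION). Per-sample fragment counts at each site are
    Poisson (or log-normal) around the site's decayed expectation, on top
    of ``background_rate`` uniformly placed background fragments per bp.
    """
    composition = dict(composition or DEFAULT_COMPOSITION)
    unknown = set(composition) - set(DEFAULT_COMPOSITION)
    if unknown:
        raise ValueError(f"unknown site categories {sorted(unknown)}")
    n_sites = sum(composition.values())
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    pfm = default_pfm() if pfm is None else np.asarray(pfm, dtype=float)
    pwm = pfm_to_pwm(pfm)
    L = pwm.length
    mid = pwm.midpoint_index
    chrom = "chrS"

    n_telomeric = composition.get("telomeric", 0)
    interior_span = genome_length - 2 * telomere_bp - 2 * min_spacing
    n_interior = n_sites - n_telomeric
    if interior_span < n_interior * min_spacing:
        raise ValueError(
            f"genome_length {genome_length} too small for {n_sites} sites "
            f"spaced >= {min_spacing} bp"
        )

    codes = _random_genome(rng, genome_length)
    telomeres = [
        GenomicInterval(chrom, 0, telomere_bp),
        GenomicInterval(chrom, genome_length - telomere_bp, genome_length),
    ]

    # summit positions: telomeric sites inside the left telomere, the rest
    # evenly spaced through the interior with jitter
    spacing = interior_span // max(n_interior, 1)
    interior = [
        telomere_bp + min_spacing + i * spacing + int(rng.integers(0, spacing // 4 + 1))
        for i in range(n_interior)
    ]
    telo_pos = [
        1000 + i * max(min_spacing, 1000) for i in range(n_telomeric)
    ]

    categories = [c for c, k in composition.items() for _ in range(k)]
    non_telo = [c for c in categories if c != "telomeric"]
    rng.shuffle(non_telo)
    placements = list(zip(telo_pos, ["telomeric"] * n_telomeric)) + list(
        zip(interior, non_telo)
    )

    truths: list[SiteTruth] = []
    peaks: list[Peak] = []
    consensus = pwm.consensus
    for i, (summit, category) in enumerate(placements):
        site_id = f"site_{i:03d}"
        koff = float(rng.uniform(*koff_range))
        y0 = float(rng.uniform(300, 1500))
        yf = float(y0 * rng.uniform(0.05, 0.15))
        strand = "+" if rng.random() < 0.5 else "-"
        if category == "low_fe":
            fe = float(rng.uniform(1.5, 3.5))
        else:
            fe = float(rng.uniform(6.0, 12.0))
        if category == "at_minus8":
            minus8 = "AT"[int(rng.integers(0, 2))]
        else:
            minus8 = "GC"[int(rng.integers(0, 2))]

        if category != "no_motif":
            _plant_motif(codes, summit, consensus, strand, mid, minus8)
            motif_seq = consensus
        else:
            motif_seq = ""
        truths.append(
            SiteTruth(
                site_id=site_id,
                chrom=chrom,
                summit=summit,
                motif_seq=motif_seq,
                motif_strand=strand,
                koff_true=koff,
                y0_true=y0,
                yf_true=yf,
                minus8_base=minus8,
                fold_enrichment_true=fe,
                telomeric=category == "telomeric",
                category=category,
            )
        )
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, summit - 150, summit + 151),
                summit=summit,
                fold_enrichment=fe,
                score=100.0,
                id=site_id,
            )
        )

    _scrub_spurious_matches(codes, rng, pwm, truths, flank=100 + L)
    genome = GenomeSequence({chrom: _to_seq(codes)})

    # fragment evidence per sample
    times = tuple(float(t) for t in times)
    fragments: dict[SampleLabel, list[GenomicInterval]] = {}
    n_background = int(round(background_rate * genome_length))
    for t in times:
        for rep in range(1, n_reps + 1):
            label = SampleLabel(time_min=t, replicate=rep, role="IP")
            frags: list[GenomicInterval] = []
            if n_background > 0:
                mids = rng.integers(200, genome_length - 200, size=n_background)
                lengths = rng.integers(120, 201, size=n_background)
                for m, ln in zip(mids, lengths):
                    start = int(m) - int(ln) // 2
                    frags.append(GenomicInterval(chrom, start, start + int(ln)))
            for truth in truths:
                mean = decay_model(t, truth.y0_true, truth.yf_true, truth.koff_true)
                if noise.kind == "poisson":
                    count = int(rng.poisson(mean))
                elif noise.kind == "lognormal":
                    sigma = np.sqrt(np.log1p(noise.sd**2)) if noise.sd > 0 else 0.0
                    count = int(round(mean * rng.lognormal(-sigma**2 / 2, sigma)))
                else:
                    count = int(round(mean))
                if count <= 0:
                    continue
                mids = np.clip(
                    rng.normal(truth.summit, 20, size=count).round().astype(int),
                    200,
                    genome_length - 200,
                )
                lengths = rng.integers(120, 201, size=count)
                for m, ln in zip(mids, lengths):
                    start = int(m) - int(ln) // 2
                    frags.append(GenomicInterval(chrom, start, start + int(ln)))
            fragments[label] = frags

    truth_df = pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "chrom": s.chrom,
                "summit": s.summit,
                "motif_strand": s.motif_strand,
                "koff_true": s.koff_true,
                "y0_true": s.y0_true,
                "yf_true": s.yf_true,
                "minus8_base": s.minus8_base,
                "fold_enrichment": s.fold_enrichment_true,
                "telomeric": s.telomeric,
                "category": s.category,
                "passes_filters": s.passes_filters,
            }
            for s in truths
        ]
    )
    return SimulatedExperiment(
        genome=genome,
        peaks=peaks,
        fragments=fragments,
        truth=truth_df,
        telomeres=telomeres,
        pfm=pfm,
        times=times,
    )


def _plant_motif(
    codes: np.ndarray,
    summit: int,
    consensus: str,
    strand: str,
    mid: int,
    minus8_base: str,
) -> None:
    """Write the consensus motif into the genome so its midpoint sits at
    ``summit`` on ``strand``, and set the -8 context base."""
    L = len(consensus)
    base_codes = np.array(["ACGT".index(b) for b in consensus], dtype=np.int8)
    m8 = "ACGT".index(minus8_base)
    if strand == "+":
        start = summit - mid
        codes[start : start + L] = base_codes
        codes[summit - 8] = m8
    else:
        rc = np.array(
            ["ACGT".index(b) for b in revcomp(consensus)], dtype=np.int8
        )
        start = summit - (L - 1 - mid)
        codes[start : start + L] = rc
        # -8 in motif orientation is summit + 8 on the genome, complemented
        codes[summit + 8] = 3 - m8


def _scrub_spurious_matches(
    codes: np.ndarray,
    rng: np.random.Generator,
    pwm: PWM,
    truths: Sequence[SiteTruth],
    flank: int,
    max_rounds: int = 50,
) -> None:
    """Re-randomize flanking sequence until each peak region contains
    exactly its planted matches (none for no-motif sites), so filter
    outcomes are forced by construction."""
    L = pwm.length
    mid = pwm.midpoint_index
    for truth in truths:
        lo = max(0, truth.summit - flank)
        hi = min(len(codes), truth.summit + flank + 1)
        if truth.motif_seq:
            if truth.motif_strand == "+":
                keep_lo = truth.summit - mid
            else:
                keep_lo = truth.summit - (L - 1 - mid)
            keep = (keep_lo, keep_lo + L)
        else:
            keep = None
        for _ in range(max_rounds):
            seq = _to_seq(codes[lo:hi])
            matches = scan_pwm(seq, pwm, chrom="x", offset=lo)
            matches = [m for m in matches if abs(m.midpoint - truth.summit) <= flank]
            expected = {truth.summit} if truth.motif_seq else set()
            spurious = [m for m in matches if m.midpoint not in expected]
            if not spurious:
                break
            for m in spurious:
                w_lo = max(lo, m.midpoint - L)
                w_hi = min(hi, m.midpoint + L)
                for pos in range(w_lo, w_hi):
                    if keep is not None and keep[0] <= pos < keep[1]:
                        continue
                    if keep is not None and pos in (
                        truth.summit - 8 if truth.motif_strand == "+" else truth.summit + 8,
                    ):
                        continue
                    codes[pos] = rng.integers(0, 4)
        else:
            raise RuntimeError(
                f"could not scrub spurious motif matches near {truth.site_id}"
            )


# ---------------------------------------------------------------------------
# auxiliary chromatin tracks


@dataclass
class SimulatedProfiles:
    occupancy: CoverageTrack
    mnase_before: CoverageTrack
    mnase_after: CoverageTrack
    polII: StrandedCoverage
    truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dio.write_track(self.occupancy, out / "occupancy.bedgraph")
        dio.write_track(self.mnase_before, out / "mnase_before.bedgraph")
        dio.write_track(self.mnase_after, out / "mnase_after.bedgraph")
        dio.write_track(self.polII.plus, out / "polII_plus.bedgraph")
        dio.write_track(self.polII.minus, out / "polII_minus.bedgraph")
        self.truth.to_csv(out / "profiles_truth.tsv", sep="\t", index=False)


def simulate_profiles(
    anchors: Sequence[Anchor],
    nfr_half_widths: Sequence[float],
    roadblock_indices: Sequence[float],
    protection_depths: Sequence[float],
    seed: int = 0,
    flank: int = 600,
    nucleosome_sd: float = 45.0,
    chrom_sizes: Mapping[str, int] | None = None,
) -> SimulatedProfiles:
    """Construct auxiliary tracks with known geometry per anchor.

    occupancy: Gaussian nucleosome bumps at +/- the NFR half-width (so the
    measured -1/+1 midpoint distance is 2 * half_width); MNase cuts:
    uniform density whose [-8, +8] motif footprint is divided by the
    protection depth before depletion and unprotected after, so the
    protection ratio equals the depth exactly; Pol II: a uniform sense-
    strand plateau with a rectangular stall component over [-42, -32]
    sized so the roadblock index equals its target, and a low antisense
    floor.
    """
    n = len(anchors)
    if not (n == len(nfr_half_widths) == len(roadblock_indices) == len(protection_depths)):
        raise ValueError("per-anchor parameter lists must match the anchor count")
    if chrom_sizes is None:
        chrom_sizes = {}
        for a in anchors:
            need = a.midpoint + flank + 10
            chrom_sizes[a.chrom] = max(chrom_sizes.get(a.chrom, 0), need)
    occupancy = CoverageTrack(chrom_sizes)
    mnase_before = CoverageTrack(chrom_sizes)
    mnase_after = CoverageTrack(chrom_sizes)
    pol_plus = CoverageTrack(chrom_sizes)
    pol_minus = CoverageTrack(chrom_sizes)

    offsets = np.arange(-flank, flank + 1)
    rows = []
    for anchor, half_width, rb_index, depth in zip(
        anchors, nfr_half_widths, roadblock_indices, protection_depths
    ):
        if anchor.midpoint - flank < 0:
            raise ValueError(f"anchor {anchor} too close to chromosome start")
        sign = 1 if anchor.strand == "+" else -1
        genome_pos = anchor.midpoint + sign * offsets  # genome position of each offset

        occ = np.exp(-0.5 * ((offsets - half_width) / nucleosome_sd) ** 2)
        occ += np.exp(-0.5 * ((offsets + half_width) / nucleosome_sd) ** 2)
        _scatter_add(occupancy[anchor.chrom], genome_pos, occ)

        cuts = np.ones_like(offsets, dtype=float)
        protected = cuts.copy()
        protected[np.abs(offsets) <= 8] /= depth
        _scatter_add(mnase_before[anchor.chrom], genome_pos, protected)
        _scatter_add(mnase_after[anchor.chrom], genome_pos, cuts)

        sense = np.ones_like(offsets, dtype=float)
        stall = (offsets >= -42) & (offsets <= -32)
        sense[stall] += rb_index - 1.0
        anti = np.full_like(sense, 0.2)
        sense_track = pol_plus if anchor.strand == "+" else pol_minus
        anti_track = pol_minus if anchor.strand == "+" else pol_plus
        _scatter_add(sense_track[anchor.chrom], genome_pos, sense)
        _scatter_add(anti_track[anchor.chrom], genome_pos, anti)

        rows.append(
            {
                "chrom": anchor.chrom,
                "midpoint": anchor.midpoint,
                "strand": anchor.strand,
                "nfr_half_width": half_width,
                "nfr_width_true": 2 * half_width,
                "roadblock_index_true": rb_index,
                "protection_depth_true": depth,
            }
        )
    return SimulatedProfiles(
        occupancy=occupancy,
        mnase_before=mnase_before,
        mnase_after=mnase_after,
        polII=StrandedCoverage(plus=pol_plus, minus=pol_minus),
        truth=pd.DataFrame(rows),
    )


def _scatter_add(arr: np.ndarray, positions: np.ndarray, values: np.ndarray) -> None:
    ok = (positions >= 0) & (positions < len(arr))
    np.add.at(arr, positions[ok], values[ok])


# ---------------------------------------------------------------------------
# nascent RNA


@dataclass
class SimulatedRna:
    counts: pd.DataFrame
    sample_times: dict[str, float]
    genes: pd.DataFrame
    truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(out / "rna_counts.tsv", sep="\t")
        self.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
        self.truth.to_csv(out / "rna_truth.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"sample": list(self.sample_times), "time_min": list(self.sample_times.values())}
        ).to_csv(out / "rna_samples.tsv", sep="\t", index=False)


def simulate_rna_experiment(
    n_down: int = 20,
    n_stable: int = 10,
    rate_range: tuple[float, float] = DEFAULT_KOFF_RANGE,
    times: Sequence[float] = DEFAULT_TIME_GRID,
    n_reps: int = 3,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> SimulatedRna:
    """Nascent-transcript counts for genes whose synthesis decays with a
    known rate after depletion, plus non-responsive genes, with a simple
    TSS annotation on a virtual chromosome."""
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    times = [float(t) for t in times]
    records: dict[str, np.ndarray] = {}
    truth_rows = []
    gene_rows = []
    for i in range(n_down + n_stable):
        gene_id = f"gene_{i:03d}"
        y0 = float(rng.uniform(400, 4000))
        if i < n_down:
            rate = float(rng.uniform(*rate_range))
            yf = float(y0 * rng.uniform(0.1, 0.3))
        else:
            rate, yf = 0.0, y0
        tc = (
            simulate_timecourse(gene_id, rate, y0, yf, times, n_reps, noise, rng)
            if rate > 0
            else TimeCourse(
                gene_id,
                np.asarray(times),
                _constant_counts(rng, noise, y0, len(times), n_reps),
            )
        )
        for r in range(n_reps):
            for j, t in enumerate(times):
                records.setdefault(f"t{t:g}_rep{r + 1}", np.zeros(n_down + n_stable))[
                    i
                ] = tc.values[r, j]
        truth_rows.append(
            {"gene_id": gene_id, "rate_true": rate, "y0_true": y0, "yf_true": yf,
             "responsive": rate > 0}
        )
        gene_rows.append(
            {"gene_id": gene_id, "chrom": "chrS", "tss": 3000 + 4000 * i,
             "strand": "+" if i % 2 == 0 else "-", "biotype": "protein_coding"}
        )
    index = [f"gene_{i:03d}" for i in range(n_down + n_stable)]
    counts = pd.DataFrame(records, index=index)
    sample_times = {
        col: float(col.split("_")[0][1:]) for col in counts.columns
    }
    return SimulatedRna(
        counts=counts,
        sample_times=sample_times,
        genes=pd.DataFrame(gene_rows),
        truth=pd.DataFrame(truth_rows),
    )


def _constant_counts(
    rng: np.random.Generator, noise: NoiseModel, level: float, n_times: int, n_reps: int
) -> np.ndarray:
    if noise.kind == "poisson":
        return rng.poisson(level, size=(n_reps, n_times)).astype(float)
    if noise.kind == "lognormal" and noise.sd > 0:
        sigma = np.sqrt(np.log1p(noise.sd**2))
        return level * rng.lognormal(-sigma**2 / 2, sigma, size=(n_reps, n_times))
    return np.full((n_reps, n_times), float(level))
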