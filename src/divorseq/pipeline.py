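"""End-to-end pipeline: fragments -> normalized matrix -> filters -> fits.

The in-memory entry point :func:`run_chip_pipeline` takes the objects the
synthetic generator produces (or that the I/O layer reads from disk) and
runs quantification, normalization, outlier flagging, site filtering,
decay fitting and quartile assignment. :func:`run_pipeline` is the
file-based driver behind the command line: it loads a config, reads every
input, calls the in-memory pipeline and writes TSV outputs plus a JSON
manifest. All thresholds live in :class:`PipelineConfig`; stage code never
hard-codes them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as dio
from .decay import DEFAULT_TIME_GRID, FitTable, TimeCourse, fit_all_sites
from .intervals import GenomicInterval, Peak
from .motifs import pfm_to_pwm
from .quant import (
    SampleLabel,
    background_fraction,
    background_normalize,
    build_midpoint_coverage,
    flag_outlier_samples,
    quantify_peaks,
    scale_track,
)
from .sites import FilterResult, filter_sites
from .tracks import GenomeSequence

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a pipeline run. Thresholds default to the
    published analysis settings."""

    # inputs
    sample_sheet: str = ""
    peaks: str = ""
    genome: str = ""
    pfm: str = ""
    telomeres: str | None = None
    chrom_sizes: str | None = None
    out_dir: str = "divorseq_out"
    # thresholds
    fe_min: float = 4.0
    min_score_frac: float = 0.85
    motif_flank: int = 100
    peak_half_width: int = 50
    smoothing_window_bp: int = 101
    target_fragments: float = 1e6
    outlier_fold_threshold: float = 6.0
    roadblock_threshold: float = 2.0
    fc_min: float = 1.5
    p_max: float = 0.01
    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID
    r2_on: str = "observations"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fe_min < 0 or not (0 < self.min_score_frac <= 1):
            raise ValueError("thresholds out of range")
        if self.smoothing_window_bp % 2 == 0:
            raise ValueError("smoothing_window_bp must be odd")
        self.time_grid = tuple(float(t) for t in self.time_grid)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything a run produces, in memory."""

    matrix: pd.DataFrame          # unfiltered peak x sample normalized values
    filter_result: FilterResult
    fits: FitTable
    flagged: list[SampleLabel]
    background_fractions: dict[SampleLabel, float]

    @property
    def cascade(self) -> list[int]:
        return self.filter_result.cascade


def run_chip_pipeline(
    genome: GenomeSequence,
    peaks: Sequence[Peak],
    fragments: Mapping[SampleLabel, Sequence[GenomicInterval]],
    pfm: np.ndarray,
    telomeres: Sequence[GenomicInterval] = (),
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run quantification, filtering and fitting on in-memory inputs.

    Background fractions are computed against the FULL unfiltered peak
    set; flagged outlier samples are excluded from the fits (their matrix
    entries become NaN).
    """
    config = config or PipelineConfig()
    chrom_sizes = genome.chrom_sizes
    ip_labels = sorted(lab for lab in fragments if lab.role == "IP")

    quantified: dict[SampleLabel, np.ndarray] = {}
    bg_fractions: dict[SampleLabel, float] = {}
    for label in ip_labels:
        frags = list(fragments[label])
        if not frags:
            raise ValueError(f"sample {label}: no fragments")
        track = build_midpoint_coverage(
            frags, chrom_sizes, window_bp=config.smoothing_window_bp
        )
        track = scale_track(track, len(frags), config.target_fragments)
        raw = quantify_peaks(track, peaks, half_width=config.peak_half_width)
        frac = background_fraction(frags, peaks)
        sample = background_normalize(
            label, raw, total_reads=len(frags),
            reads_in_peaks=round(len(frags) * (1 - frac)),
        )
        quantified[label] = sample.normalized
        bg_fractions[label] = sample.background_fraction
        logger.info("quantified %s (background fraction %.3f)", label, frac)

    flagged = flag_outlier_samples(
        quantified, fold_threshold=config.outlier_fold_threshold
    )
    for label in flagged:
        logger.info("excluding flagged sample %s from fitting", label)

    matrix = pd.DataFrame(
        {str(lab): quantified[lab] for lab in ip_labels},
        index=[p.id for p in peaks],
    )

    filter_result = filter_sites(
        peaks,
        genome,
        pfm_to_pwm(pfm),
        fe_min=config.fe_min,
        motif_flank=config.motif_flank,
        min_score_frac=config.min_score_frac,
        telomeres=telomeres,
    )
    logger.info("filter cascade: %s", " -> ".join(map(str, filter_result.cascade)))

    times = sorted({lab.time_min for lab in ip_labels})
    reps = sorted({lab.replicate for lab in ip_labels})
    flagged_set = set(flagged)
    peak_index = {p.id: i for i, p in enumerate(peaks)}
    timecourses = []
    for site in filter_result.sites:
        row = peak_index[site.id]
        values = np.full((len(reps), len(times)), np.nan)
        for lab in ip_labels:
            if lab in flagged_set:
                continue
            values[reps.index(lab.replicate), times.index(lab.time_min)] = quantified[
                lab
            ][row]
        timecourses.append(
            TimeCourse(site_id=site.id, times=np.asarray(times), values=values)
        )

    fits = fit_all_sites(timecourses, r2_on=config.r2_on)
    for site in filter_result.sites:
        if site.id in fits.table.index:
            site.quartile = fits.table.loc[site.id, "quartile"]
    return PipelineResult(
        matrix=matrix,
        filter_result=filter_result,
        fits=fits,
        flagged=flagged,
        background_fractions=bg_fractions,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based driver: read all configured inputs, run the pipeline and
    write results (sites, matrix, fits, summary manifest) to
    ``config.out_dir``."""
    genome = dio.read_fasta(config.genome)
    peaks = dio.read_peaks(config.peaks)
    pfm = dio.read_pfm(config.pfm)
    telomeres = (
        dio.read_fragments(config.telomeres) if config.telomeres else []
    )
    sheet = dio.read_sample_sheet(config.sample_sheet)
    base = Path(config.sample_sheet).parent
    fragments: dict[SampleLabel, list[GenomicInterval]] = {}
    for _, row in sheet.iterrows():
        label = SampleLabel(
            time_min=float(row["time_min"]),
            replicate=int(row["replicate"]),
            role=str(row["role"]),
        )
        path = Path(row["path"])
        fragments[label] = dio.read_fragments(path if path.is_absolute() else base / path)

    result = run_chip_pipeline(
        genome, peaks, fragments, pfm, telomeres=telomeres, config=config
    )
    write_results(result, config)
    return result


def write_results(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.matrix.to_csv(out / "binding_matrix.tsv", sep="\t")
    result.fits.table.to_csv(out / "fits.tsv", sep="\t")
    result.fits.residuals.to_csv(out / "fit_residuals.tsv", sep="\t")

    rows = []
    for site in result.filter_result.sites + result.filter_result.dropped:
        rows.append(
            {
                "site_id": site.id,
                "chrom": site.peak.chrom,
                "summit": site.peak.summit,
                "fold_enrichment": site.peak.fold_enrichment,
                "n_motifs": len(site.motif_matches),
                "best_score_frac": (
                    site.best.score_frac if site.motif_matches else np.nan
                ),
                "passed": site.passed,
                "excluded_reason": site.excluded_reason or "",
                "quartile": site.quartile or "",
            }
        )
    pd.DataFrame(rows).to_csv(out / "sites.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "config_digest": config.digest(),
        "cascade": result.cascade,
        "flagged_samples": [str(lab) for lab in result.flagged],
        "n_sites": len(result.filter_result.sites),
        "fit_summary": result.fits.summary if len(result.fits.table) else {},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
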