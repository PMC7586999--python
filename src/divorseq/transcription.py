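"""Nascent-RNA time-course processing.

Links binding kinetics to transcriptional output: median normalization of
per-gene nascent transcript counts (rRNA excluded), selection of genes
responding to factor depletion from an externally computed
differential-expression table, promoter assignment of binding sites to
genes, and fitting of the same first-order decay model to the synthesis
time course of each downregulated gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .decay import DecayFit, TimeCourse, fit_decay
from .sites import BindingSite

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRecord:
    """Minimal gene annotation: TSS position, strand and biotype (the
    biotype is what identifies rRNA genes for count filtering)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be + or -")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


def normalize_counts_median(
    counts: pd.DataFrame, biotypes: Mapping[str, str]
) -> pd.DataFrame:
    """Median-of-totals normalization of a gene x sample count matrix.

    rRNA genes are removed first; each sample is then scaled by
    (median of post-filter per-sample totals) / (its own total), so the
    median sample is left unchanged.
    """
    is_rrna = counts.index.map(lambda g: biotypes.get(g, "") == "rRNA")
    filtered = counts.loc[~is_rrna]
    if filtered.empty:
        raise ValueError("no non-rRNA genes left after filtering")
    totals = filtered.sum(axis=0)
    if (totals == 0).any():
        zero = list(totals.index[totals == 0])
        raise ValueError(f"samples with zero total counts: {zero}")
    return filtered * (float(totals.median()) / totals)


@dataclass
class ResponsiveGenes:
    """Depletion-responsive gene sets with per-gene response-strength
    labels (from the magnitude of the fold change at the early required
    time point): 'strong' (> 2x), 'weak' (1.5-2x), 'none' (< 1.5x)."""

    down: set[str]
    up: set[str]
    unchanged: set[str]
    strength: dict[str, str]


def select_responsive_genes(
    de: pd.DataFrame,
    fc_min: float = 1.5,
    p_max: float = 0.01,
    required_times: Sequence[float] = (20.0, 30.0),
    strength_time: float = 20.0,
) -> ResponsiveGenes:
    """Classify genes from a differential-expression table.

    ``de`` needs columns gene_id, time_min, fold_change (linear, relative
    to t = 0) and padj. A gene is downregulated iff fold_change < 1/fc_min
    with padj < p_max at EVERY required time point (strict inequalities);
    upregulated symmetrically. Genes missing a required time point are
    skipped with a warning.
    """
    for col in ("gene_id", "time_min", "fold_change", "padj"):
        if col not in de.columns:
            raise ValueError(f"DE table missing column {col!r}")
    if (de["fold_change"] <= 0).any():
        raise ValueError("fold changes must be positive (linear scale)")

    down, up, unchanged = set(), set(), set()
    strength: dict[str, str] = {}
    for gene_id, sub in de.groupby("gene_id"):
        by_time = sub.set_index("time_min")
        if any(t not in by_time.index for t in required_times):
            logger.warning("gene %s missing a required time point; skipped", gene_id)
            continue
        rows = by_time.loc[list(required_times)]
        is_down = bool(
            ((rows["fold_change"] < 1.0 / fc_min) & (rows["padj"] < p_max)).all()
        )
        is_up = bool(
            ((rows["fold_change"] > fc_min) & (rows["padj"] < p_max)).all()
        )
        if is_down:
            down.add(gene_id)
        elif is_up:
            up.add(gene_id)
        else:
            unchanged.add(gene_id)
        if strength_time in by_time.index:
            fc = float(by_time.loc[strength_time, "fold_change"])
            magnitude = max(fc, 1.0 / fc)
            if magnitude > 2.0:
                strength[gene_id] = "strong"
            elif magnitude >= fc_min:
                strength[gene_id] = "weak"
            else:
                strength[gene_id] = "none"
    return ResponsiveGenes(down=down, up=up, unchanged=unchanged, strength=strength)


def assign_peak_to_gene(
    sites: Sequence[BindingSite],
    genes: Sequence[GeneRecord],
    promoter_bp: int = 500,
) -> dict[str, str]:
    """Map gene_id -> site_id for sites whose summit lies in the promoter.

    The promoter is the ``promoter_bp`` bases immediately upstream of the
    TSS: [tss - promoter_bp, tss) for + strand genes, (tss, tss +
    promoter_bp] for - strand genes (the TSS itself is excluded). When
    several site summits fall in one promoter, the summit nearest the TSS
    wins.
    """
    assignment: dict[str, str] = {}
    for gene in genes:
        candidates = []
        for site in sites:
            if site.peak.chrom != gene.chrom:
                continue
            s = site.peak.summit
            if gene.strand == "+":
                in_promoter = gene.tss - promoter_bp <= s < gene.tss
            else:
                in_promoter = gene.tss < s <= gene.tss + promoter_bp
            if in_promoter:
                candidates.append((abs(s - gene.tss), site.id))
        if candidates:
            assignment[gene.gene_id] = min(candidates)[1]
    return assignment


def fit_synthesis_decay(gene_tc: TimeCourse) -> DecayFit:
    """Fit the binding-decay model to a gene's normalized synthesis time
    course; here y_0 is the pre-depletion expression level and k_off the
    rate at which expression falls to its new level y_f."""
    return fit_decay(gene_tc)


@dataclass
class SynthesisFits:
    fits: dict[str, DecayFit]
    unfittable: dict[str, str]


def fit_synthesis_batch(timecourses: Iterable[TimeCourse]) -> SynthesisFits:
    """Fit every gene; genes where no reliable fit is obtained (errors or
    non-convergence) are reported as unfittable rather than aborting."""
    fits: dict[str, DecayFit] = {}
    unfittable: dict[str, str] = {}
    for tc in timecourses:
        try:
            fit = fit_synthesis_decay(tc)
        except Exception as exc:  # noqa: BLE001
            unfittable[tc.site_id] = str(exc)
            continue
        if fit.converged:
            fits[tc.site_id] = fit
        else:
            unfittable[tc.site_id] = "non-converged fit"
    return SynthesisFits(fits=fits, unfittable=unfittable)


def differential_expression_ttest(
    norm_counts: pd.DataFrame,
    sample_times: Mapping[str, float],
) -> pd.DataFrame:
    """Minimal fallback differential-expression table for synthetic
    end-to-end runs: per gene and time point, a two-sided t-test of log
    counts versus t = 0 with Benjamini-Hochberg adjustment across genes.

    This is NOT equivalent to a negative-binomial DE model on real count
    data; real analyses should supply an externally computed table.
    """
    from scipy import stats
    from statsmodels.stats.multitest import multipletests

    times = sorted({t for t in sample_times.values() if t > 0})
    t0_cols = [c for c in norm_counts.columns if sample_times[c] == 0]
    if not t0_cols:
        raise ValueError("no t = 0 samples")
    log0 = np.log2(norm_counts[t0_cols] + 1.0)
    records = []
    for t in times:
        cols = [c for c in norm_counts.columns if sample_times[c] == t]
        logt = np.log2(norm_counts[cols] + 1.0)
        fc = (2.0 ** (logt.mean(axis=1) - log0.mean(axis=1))).to_numpy()
        pvals = np.array(
            [
                stats.ttest_ind(logt.loc[g], log0.loc[g]).pvalue
                if logt.loc[g].std() + log0.loc[g].std() > 0
                else 1.0
                for g in norm_counts.index
            ]
        )
        pvals = np.nan_to_num(pvals, nan=1.0)
        padj = multipletests(pvals, method="fdr_bh")[1]
        for gene, f, p in zip(norm_counts.index, fc, padj):
            records.append(
                {"gene_id": gene, "time_min": t, "fold_change": float(f),
                 "padj": float(p)}
            )
    return pd.DataFrame.from_records(records)
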