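"""Nascent-RNA normalization, gene selection and synthesis-decay fits."""

import numpy as np
import pandas as pd
import pytest

from divorseq.decay import DEFAULT_TIME_GRID, TimeCourse, decay_model
from divorseq.intervals import GenomicInterval, Peak
from divorseq.sites import BindingSite
from divorseq.transcription import (
    GeneRecord,
    assign_peak_to_gene,
    differential_expression_ttest,
    fit_synthesis_batch,
    fit_synthesis_decay,
    normalize_counts_median,
    select_responsive_genes,
)

TIMES = np.asarray(DEFAULT_TIME_GRID)


class TestMedianNormalization:
    def test_constructed_scale_factors(self):
        counts = pd.DataFrame(
            {"s1": [60, 40], "s2": [200, 100], "s3": [150, 50]},
            index=["g1", "g2"],
        )
        # totals 100, 300, 200 -> median 200 -> factors 2, 2/3, 1
        norm = normalize_counts_median(counts, {})
        np.testing.assert_allclose(norm["s1"], [120, 80])
        np.testing.assert_allclose(norm["s2"], [400 / 3, 200 / 3])
        np.testing.assert_allclose(norm["s3"], [150, 50])

    def test_equal_totals_identity(self):
        counts = pd.DataFrame({"s1": [10, 20], "s2": [5, 25]}, index=["g1", "g2"])
        norm = normalize_counts_median(counts, {})
        pd.testing.assert_frame_equal(norm, counts.astype(float))

    def test_rrna_removed_before_totals(self):
        counts = pd.DataFrame(
            {"s1": [100, 900], "s2": [300, 100]}, index=["g1", "rdn"]
        )
        norm = normalize_counts_median(counts, {"rdn": "rRNA"})
        assert list(norm.index) == ["g1"]
        # post-filter totals 100 and 300, median 200
        np.testing.assert_allclose(norm.loc["g1"], [200.0, 200.0])

    def test_only_rrna_errors(self):
        counts = pd.DataFrame({"s1": [5]}, index=["rdn"])
        with pytest.raises(ValueError, match="non-rRNA"):
            normalize_counts_median(counts, {"rdn": "rRNA"})

    def test_zero_total_sample_errors(self):
        counts = pd.DataFrame({"s1": [5], "s2": [0]}, index=["g1"])
        with pytest.raises(ValueError, match="zero total"):
            normalize_counts_median(counts, {})

    def test_median_sample_unchanged(self, rng):
        counts = pd.DataFrame(
            rng.integers(10, 500, size=(20, 5)).astype(float),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(5)],
        )
        norm = normalize_counts_median(counts, {})
        factors = norm.sum(axis=0) / counts.sum(axis=0)
        assert factors.min() <= 1.0 <= factors.max()


def de_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "time_min", "fold_change", "padj"])


class TestResponsiveGenes:
    def test_down_at_both_required_times(self):
        de = de_table([("g1", 20.0, 0.4, 0.001), ("g1", 30.0, 0.4, 0.002)])
        result = select_responsive_genes(de)
        assert result.down == {"g1"}
        assert result.strength["g1"] == "strong"  # magnitude 2.5 > 2

    def test_exactly_twofold_is_weak(self):
        de = de_table([("g1", 20.0, 0.5, 0.001), ("g1", 30.0, 0.5, 0.001)])
        assert select_responsive_genes(de).strength["g1"] == "weak"

    def test_failing_one_time_point_not_selected(self):
        de = de_table([("g1", 20.0, 0.5, 0.001), ("g1", 30.0, 0.5, 0.05)])
        result = select_responsive_genes(de)
        assert result.down == set()
        assert "g1" in result.unchanged

    def test_hand_evaluated_ten_gene_table(self):
        rows = []
        spec = {
            "down_strong": (0.3, 0.001), "down_weak": (0.6, 0.001),
            "up": (3.0, 0.001), "flat": (1.0, 0.9),
            "p_fail": (0.3, 0.02), "fc_fail": (0.8, 0.001),
        }
        for gene, (fc, p) in spec.items():
            rows += [(gene, 20.0, fc, p), (gene, 30.0, fc, p)]
        result = select_responsive_genes(de_table(rows))
        assert result.down == {"down_strong", "down_weak"}
        assert result.up == {"up"}
        assert result.unchanged == {"flat", "p_fail", "fc_fail"}
        assert result.strength["down_strong"] == "strong"
        assert result.strength["down_weak"] == "weak"
        assert result.strength["flat"] == "none"

    def test_missing_required_time_skipped_with_warning(self, caplog):
        de = de_table([("g1", 20.0, 0.5, 0.001)])
        with caplog.at_level("WARNING"):
            result = select_responsive_genes(de)
        assert result.down == set() and "g1" not in result.unchanged

    def test_monotone_in_thresholds(self, rng):
        rows = []
        for i in range(40):
            fc = float(rng.uniform(0.2, 1.2))
            p = float(rng.uniform(0, 0.05))
            rows += [(f"g{i}", 20.0, fc, p), (f"g{i}", 30.0, fc, p)]
        de = de_table(rows)
        strict = select_responsive_genes(de, fc_min=2.0, p_max=0.005).down
        loose = select_responsive_genes(de, fc_min=1.2, p_max=0.02).down
        assert strict <= loose


def site_at(summit, chrom="chrI", sid="s1"):
    peak = Peak(GenomicInterval(chrom, summit - 50, summit + 51), summit, 8.0, id=sid)
    return BindingSite(peak=peak)


class TestPromoterAssignment:
    def test_plus_strand_upstream_window(self):
        genes = [GeneRecord("g1", "chrI", 1000, "+")]
        assert assign_peak_to_gene([site_at(700)], genes) == {"g1": "s1"}
        assert assign_peak_to_gene([site_at(499)], genes) == {}

    def test_summit_at_tss_excluded(self):
        genes = [GeneRecord("g1", "chrI", 1000, "+")]
        assert assign_peak_to_gene([site_at(1000)], genes) == {}

    def test_minus_strand_promoter_is_genomically_downstream(self):
        genes = [GeneRecord("g1", "chrI", 1000, "-")]
        assert assign_peak_to_gene([site_at(1300)], genes) == {"g1": "s1"}
        assert assign_peak_to_gene([site_at(700)], genes) == {}

    def test_nearest_summit_wins(self):
        genes = [GeneRecord("g1", "chrI", 1000, "+")]
        sites = [site_at(600, sid="far"), site_at(900, sid="near")]
        assert assign_peak_to_gene(sites, genes) == {"g1": "near"}


class TestSynthesisDecay:
    def test_noiseless_recovery(self):
        curve = decay_model(TIMES, 1000, 200, 0.08)
        tc = TimeCourse("g1", TIMES, np.tile(curve, (3, 1)))
        fit = fit_synthesis_decay(tc)
        assert fit.koff == pytest.approx(0.08, rel=1e-6)

    def test_constant_expression_reported_unfittable(self):
        flat = TimeCourse("g1", TIMES, np.full((3, len(TIMES)), 500.0))
        curve = decay_model(TIMES, 1000, 200, 0.08)
        ok = TimeCourse("g2", TIMES, np.tile(curve, (3, 1)))
        result = fit_synthesis_batch([flat, ok])
        assert set(result.fits) == {"g2"}
        assert "g1" in result.unfittable

    def test_batch_rank_correlation_with_truth(self, rng):
        from scipy.stats import spearmanr

        rates, tcs = [], []
        for i in range(12):
            rate = float(rng.uniform(0.03, 0.24))
            y0 = float(rng.uniform(500, 3000))
            curve = decay_model(TIMES, y0, 0.2 * y0, rate)
            noisy = rng.poisson(np.tile(curve, (3, 1))).astype(float)
            rates.append(rate)
            tcs.append(TimeCourse(f"g{i}", TIMES, noisy))
        result = fit_synthesis_batch(tcs)
        fitted = [result.fits[f"g{i}"].koff for i in range(12)]
        assert spearmanr(rates, fitted).statistic > 0.95


class TestFallbackDE:
    def test_detects_synthetic_downregulation(self, rng):
        genes = [f"g{i}" for i in range(12)]
        cols, times = {}, {}
        for t in (0.0, 20.0, 30.0):
            for rep in (1, 2, 3):
                name = f"t{t:g}_r{rep}"
                times[name] = t
                level = np.where(np.arange(12) < 6, 1000 * (0.3 if t > 0 else 1), 1000)
                cols[name] = rng.poisson(level).astype(float)
        counts = pd.DataFrame(cols, index=genes)
        de = differential_expression_ttest(counts, times)
        result = select_responsive_genes(de)
        assert result.down == {f"g{i}" for i in range(6)}
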