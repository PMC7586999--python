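"""Motif-anchored profiles and residence-time-stratified metrics."""

import itertools

import numpy as np
import pytest

from divorseq.chromatin import (
    Anchor,
    aggregate_profile,
    extract_site_signal,
    group_compare,
    mnase_protection_ratio,
    moving_average,
    nfr_width,
    roadblock_index,
)
from divorseq.simulate import simulate_profiles
from divorseq.tracks import CoverageTrack, StrandedCoverage


def ramp_track(n=2000):
    return CoverageTrack.from_arrays({"chrI": np.arange(n, dtype=float)})


class TestAggregateProfile:
    def test_plus_anchor_reproduces_ramp_segment(self):
        prof = aggregate_profile(ramp_track(), [Anchor("chrI", 1000, "+")], flank=10)
        np.testing.assert_array_equal(prof.mean, np.arange(990, 1011))
        assert prof.n_sites == 1 and (prof.sem == 0).all()

    def test_minus_anchor_reverses_segment(self):
        prof = aggregate_profile(ramp_track(), [Anchor("chrI", 1000, "-")], flank=10)
        np.testing.assert_array_equal(prof.mean, np.arange(1010, 989, -1))

    def test_reorienting_twice_restores_signal(self):
        vec = extract_site_signal(ramp_track(), Anchor("chrI", 500, "-"), 50)
        np.testing.assert_array_equal(
            vec[::-1], extract_site_signal(ramp_track(), Anchor("chrI", 500, "+"), 50)
        )

    def test_matches_direct_extraction_and_mean(self, rng):
        arr = rng.random(5000)
        track = CoverageTrack.from_arrays({"chrI": arr})
        anchors = [
            Anchor("chrI", int(p), "+" if i % 2 else "-")
            for i, p in enumerate(rng.integers(200, 4800, 20))
        ]
        prof = aggregate_profile(track, anchors, flank=100)
        direct = []
        for a in anchors:
            seg = arr[a.midpoint - 100 : a.midpoint + 101]
            direct.append(seg[::-1] if a.strand == "-" else seg)
        direct = np.stack(direct)
        np.testing.assert_allclose(prof.mean, direct.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(
            prof.sem, direct.std(axis=0, ddof=1) / np.sqrt(20), atol=1e-12
        )

    def test_stranded_pair_swaps_on_minus_anchor(self):
        plus = CoverageTrack.from_arrays({"chrI": np.arange(100.0)})
        minus = CoverageTrack.from_arrays({"chrI": np.arange(100.0) * 10})
        pair = StrandedCoverage(plus=plus, minus=minus)
        sense_plus = extract_site_signal(pair, Anchor("chrI", 50, "+"), 5)
        sense_minus = extract_site_signal(pair, Anchor("chrI", 50, "-"), 5)
        np.testing.assert_array_equal(sense_plus, np.arange(45.0, 56.0))
        np.testing.assert_array_equal(sense_minus, np.arange(550.0, 440.0, -10.0))

    def test_mirror_symmetric_track_gives_palindromic_profile(self):
        n = 401
        sym = np.exp(-0.5 * ((np.arange(n) - 200) / 30.0) ** 2)
        track = CoverageTrack.from_arrays({"chrI": sym})
        prof = aggregate_profile(
            track, [Anchor("chrI", 200, "+"), Anchor("chrI", 200, "-")], flank=150
        )
        np.testing.assert_allclose(prof.mean, prof.mean[::-1], atol=1e-12)

    def test_out_of_bounds_anchor_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            prof = aggregate_profile(
                ramp_track(), [Anchor("chrI", 5, "+"), Anchor("chrI", 1000, "+")],
                flank=50,
            )
        assert prof.n_sites == 1
        assert "dropped" in caplog.text

    def test_empty_anchor_set_errors(self):
        with pytest.raises(ValueError):
            aggregate_profile(ramp_track(), [], flank=10)

    def test_smoothing_window(self):
        track = CoverageTrack.from_arrays({"chrI": np.zeros(201)})
        track["chrI"][100] = 3.0
        prof = aggregate_profile(track, [Anchor("chrI", 100, "+")], 10, smooth_bp=3)
        assert prof.mean[10] == pytest.approx(1.0)
        assert prof.mean[9] == pytest.approx(1.0)


class TestMnaseProtection:
    ANCHOR = Anchor("chrI", 500, "+")

    def test_identical_tracks_ratio_one(self):
        track = CoverageTrack.from_arrays({"chrI": np.ones(1000)})
        assert mnase_protection_ratio(track, track, self.ANCHOR) == pytest.approx(1.0)

    def test_threefold_increase(self):
        before = CoverageTrack.from_arrays({"chrI": np.ones(1000)})
        after = CoverageTrack.from_arrays({"chrI": np.full(1000, 3.0)})
        assert mnase_protection_ratio(before, after, self.ANCHOR) == pytest.approx(3.0)

    def test_zero_cuts_excluded(self):
        zero = CoverageTrack.from_arrays({"chrI": np.zeros(1000)})
        some = CoverageTrack.from_arrays({"chrI": np.ones(1000)})
        assert mnase_protection_ratio(zero, some, self.ANCHOR) is None
        assert mnase_protection_ratio(some, zero, self.ANCHOR) is None


def two_bump_profile(half_width, flank=500, sd=45.0, rng=None, noise=0.0):
    offsets = np.arange(-flank, flank + 1)
    occ = np.exp(-0.5 * ((offsets - half_width) / sd) ** 2)
    occ += np.exp(-0.5 * ((offsets + half_width) / sd) ** 2)
    if noise:
        occ = np.clip(occ + rng.normal(0, noise, occ.shape), 0, None)
    return occ


class TestNfrWidth:
    @pytest.mark.parametrize("half,expected", [(154, 308), (136, 272)])
    def test_constructed_widths(self, half, expected):
        assert nfr_width(two_bump_profile(half)) == expected

    def test_noisy_profile_within_five_bp(self, rng):
        width = nfr_width(two_bump_profile(150, rng=rng, noise=0.05))
        assert abs(width - 300) <= 10  # each maximum within +/- 5 bp

    def test_scale_invariance(self):
        occ = two_bump_profile(140)
        assert nfr_width(occ) == nfr_width(occ * 17.3)

    def test_missing_flanking_nucleosome_errors(self):
        offsets = np.arange(-500, 501)
        one_sided = np.exp(-0.5 * ((offsets - 150) / 45.0) ** 2)
        with pytest.raises(ValueError, match="no flanking nucleosome"):
            nfr_width(one_sided)

    def test_supplied_dyads_take_precedence(self):
        occ = two_bump_profile(154)
        assert nfr_width(occ, dyads=(-120, 160)) == 280

    def test_requires_400bp_coverage(self):
        with pytest.raises(ValueError, match="400"):
            nfr_width(two_bump_profile(100, flank=200))


def uniform_polII(n=2000, sense_value=1.0, stall=None):
    """Plus-strand track with optional elevated [lo, hi] offset window
    around position 1000."""
    plus = np.full(n, sense_value)
    if stall is not None:
        lo, hi, value = stall
        plus[1000 + lo : 1000 + hi + 1] = value
    return StrandedCoverage(
        plus=CoverageTrack.from_arrays({"chrI": plus}),
        minus=CoverageTrack.from_arrays({"chrI": np.full(n, 0.1)}),
    )


class TestRoadblockIndex:
    ANCHOR = Anchor("chrI", 1000, "+")

    def test_uniform_signal_index_one(self):
        result = roadblock_index(uniform_polII(), self.ANCHOR)
        assert result.index == pytest.approx(1.0)
        assert result.is_roadblock is False

    def test_elevated_stall_window(self):
        result = roadblock_index(uniform_polII(stall=(-42, -32, 3.0)), self.ANCHOR)
        assert result.index == pytest.approx(3.0)
        assert result.is_roadblock is True

    def test_exactly_two_is_not_roadblock(self):
        result = roadblock_index(uniform_polII(stall=(-42, -32, 2.0)), self.ANCHOR)
        assert result.index == pytest.approx(2.0)
        assert result.is_roadblock is False

    def test_global_scaling_invariance(self):
        pair = uniform_polII(stall=(-42, -32, 3.0))
        scaled = StrandedCoverage(plus=pair.plus.scaled(7.0), minus=pair.minus.scaled(7.0))
        a = roadblock_index(pair, self.ANCHOR).index
        b = roadblock_index(scaled, self.ANCHOR).index
        assert a == pytest.approx(b)

    def test_zero_upstream_excluded_with_reason(self):
        pair = uniform_polII(sense_value=0.0)
        result = roadblock_index(pair, self.ANCHOR)
        assert result.index is None and result.reason

    def test_minus_anchor_uses_minus_strand(self):
        # stall upstream in motif orientation = genomically downstream
        minus = np.full(2000, 1.0)
        minus[1032:1043] = 3.0  # offsets [-42, -32] map to 1032..1042
        pair = StrandedCoverage(
            plus=CoverageTrack.from_arrays({"chrI": np.full(2000, 0.1)}),
            minus=CoverageTrack.from_arrays({"chrI": minus}),
        )
        result = roadblock_index(pair, Anchor("chrI", 1000, "-"))
        assert result.index == pytest.approx(3.0)


class TestGroupCompare:
    def test_identical_groups_large_p(self, rng):
        values = np.tile(rng.normal(10, 1, 30), 2)
        groups = ["a"] * 30 + ["b"] * 30
        for test in ("anova_tukey", "ttest", "wilcoxon"):
            assert group_compare(values, groups, test=test).p_value > 0.5

    def test_shifted_groups_tiny_p(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(10, 1, 30)
        values = np.concatenate([a, b])
        groups = ["a"] * 30 + ["b"] * 30
        assert group_compare(values, groups, test="ttest").p_value < 1e-6
        assert group_compare(values, groups, test="anova_tukey").p_value < 1e-6

    def test_tukey_pairwise_table(self, rng):
        values = np.concatenate([rng.normal(m, 1, 12) for m in (0, 0.2, 5, 5.1)])
        groups = np.repeat(["longest", "long", "short", "shortest"], 12)
        result = group_compare(values, groups, test="anova_tukey")
        assert len(result.pairwise) == 6  # all quartile contrasts
        assert {"group1", "group2", "p-adj"} <= set(result.pairwise.columns)

    def test_wilcoxon_matches_exact_permutation(self):
        a, b = [1.0, 3.0], [2.0, 4.0]
        got = group_compare(a + b, ["a", "a", "b", "b"], test="wilcoxon").p_value
        # exact two-sided rank-sum p by full enumeration of group splits
        pooled = sorted(a + b)
        ranks = {v: i + 1 for i, v in enumerate(pooled)}
        obs = sum(ranks[v] for v in a)
        stats = [
            sum(ranks[pooled[i]] for i in combo)
            for combo in itertools.combinations(range(4), 2)
        ]
        mean = np.mean(stats)
        expected = np.mean([abs(s - mean) >= abs(obs - mean) - 1e-12 for s in stats])
        assert got == pytest.approx(expected)

    def test_degenerate_group_named_in_error(self):
        with pytest.raises(ValueError, match="b"):
            group_compare([1, 2, 3], ["a", "a", "b"], test="ttest")


class TestGeneratorRoundTrips:
    def test_profiles_recover_planted_parameters(self):
        anchors = [Anchor("chrS", 2000, "+"), Anchor("chrS", 6000, "-")]
        sim = simulate_profiles(
            anchors,
            nfr_half_widths=[154, 136],
            roadblock_indices=[3.0, 1.5],
            protection_depths=[2.0, 1.2],
        )
        prof_a = aggregate_profile(sim.occupancy, [anchors[0]], flank=500)
        prof_b = aggregate_profile(sim.occupancy, [anchors[1]], flank=500)
        assert nfr_width(prof_a) == 308
        assert nfr_width(prof_b) == 272
        assert mnase_protection_ratio(
            sim.mnase_before, sim.mnase_after, anchors[0]
        ) == pytest.approx(2.0, abs=1e-9)
        assert roadblock_index(sim.polII, anchors[0]).index == pytest.approx(3.0)
        assert roadblock_index(sim.polII, anchors[1]).index == pytest.approx(1.5)
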