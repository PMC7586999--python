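"""PWM construction, scanning and motif-composition statistics."""

import itertools
import math

import numpy as np
import pytest

from divorseq.motifs import (
    MotifMatch,
    annotate_minus8,
    best_match,
    consensus_counts,
    pfm_to_pwm,
    position_enrichment_test,
    scan_pwm,
)
from divorseq.tracks import GenomeSequence, revcomp

BASES = "ACGT"


def brute_force_scan(seq, pwm, min_score_frac):
    """Independent oracle: enumerate every window on both strands and score
    it base by base with plain Python."""
    L = pwm.length
    mid = pwm.midpoint_index
    hits = []
    for s in range(len(seq) - L + 1):
        window = seq[s : s + L]
        for strand, w in (("+", window), ("-", revcomp(window))):
            score = 0.0
            for i, base in enumerate(w):
                col = pwm.weights[:, i]
                score += col[BASES.index(base)] if base in BASES else col.min()
            if score >= min_score_frac * pwm.max_score:
                midpoint = s + mid if strand == "+" else s + (L - 1 - mid)
                hits.append((midpoint, strand, round(score, 6)))
    return sorted(hits)


class TestPfmToPwm:
    def test_single_column(self):
        pwm = pfm_to_pwm(np.array([[1.0], [0.0], [0.0], [0.0]]))
        assert list(pwm.weights[:, 0]) == [1000.0, 0.0, 0.0, 0.0]
        assert pwm.max_score == 1000.0

    def test_uniform_pfm_degenerate(self):
        pwm = pfm_to_pwm(np.full((4, 3), 5.0))
        assert pwm.max_score == pwm.min_score
        for seq in ("AAA", "CGT", "TTT"):
            assert pwm.score(seq) == pytest.approx(pwm.max_score)

    def test_max_score_matches_trinucleotide_enumeration(self, rng):
        pfm = rng.random((4, 3)) + 0.01
        pwm = pfm_to_pwm(pfm)
        best = max(
            pwm.score("".join(tri)) for tri in itertools.product(BASES, repeat=3)
        )
        assert pwm.max_score == pytest.approx(best)

    def test_all_zero_column_rejected(self):
        pfm = np.ones((4, 2))
        pfm[:, 1] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            pfm_to_pwm(pfm)


class TestScanPwm:
    def test_consensus_scores_exactly_one(self, pwm):
        matches = scan_pwm(pwm.consensus, pwm)
        plus = [m for m in matches if m.strand == "+"]
        assert len(plus) == 1
        assert plus[0].score_frac == pytest.approx(1.0)
        assert plus[0].midpoint == pwm.midpoint_index

    def test_reverse_complement_mirrors_midpoint(self, pwm):
        L = pwm.length
        matches = scan_pwm(revcomp(pwm.consensus), pwm)
        minus = [m for m in matches if m.strand == "-"]
        assert len(minus) == 1
        assert minus[0].score_frac == pytest.approx(1.0)
        assert minus[0].midpoint == L - 1 - pwm.midpoint_index

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pfm = rng.random((4, 2)) + 0.05
        pwm = pfm_to_pwm(pfm)
        seq = "".join(rng.choice(list("ACGTN"), size=300, p=[0.24] * 4 + [0.04]))
        got = sorted(
            (m.midpoint, m.strand, round(m.score, 6))
            for m in scan_pwm(seq, pwm, min_score_frac=0.8)
        )
        assert got == brute_force_scan(seq, pwm, 0.8)

    def test_revcomp_involution(self, pwm, rng):
        """Reverse-complementing the sequence maps every match to the
        strand-flipped mirrored coordinate."""
        seq = "".join(rng.choice(list(BASES), size=200))
        seq = seq[:50] + pwm.consensus + seq[50:]
        n = len(seq)
        fwd = scan_pwm(seq, pwm)
        rc = scan_pwm(revcomp(seq), pwm)
        mapped = sorted(
            (n - 1 - m.midpoint, "+-"[m.strand == "+"], round(m.score, 6)) for m in rc
        )
        orig = sorted((m.midpoint, m.strand, round(m.score, 6)) for m in fwd)
        assert mapped == orig

    def test_n_scores_worst_case(self, pwm):
        seq = pwm.consensus.replace(pwm.consensus[0], "N", 1)
        matches = scan_pwm(seq, pwm, min_score_frac=0.0, both_strands=False)
        col0 = pwm.weights[:, 0]
        expected = pwm.max_score - col0.max() + col0.min()
        assert matches[0].score == pytest.approx(expected)

    def test_short_sequence_empty(self, pwm):
        assert scan_pwm("ACG", pwm) == []

    def test_offset_shifts_coordinates(self, pwm):
        m0 = scan_pwm(pwm.consensus, pwm)[0]
        m1 = scan_pwm(pwm.consensus, pwm, offset=500, chrom="chrI")[0]
        assert m1.midpoint == m0.midpoint + 500
        assert m1.chrom == "chrI"


class TestBestMatch:
    def mk(self, score, midpoint=0, strand="+"):
        return MotifMatch("chrI", midpoint, strand, score, score / 1000)

    def test_highest_score_wins(self):
        assert best_match([self.mk(900), self.mk(950)]).score == 950

    def test_single_match_identity(self):
        m = self.mk(10)
        assert best_match([m]) is m

    def test_tie_broken_by_summit_distance_then_strand(self):
        near = self.mk(900, midpoint=110)
        far = self.mk(900, midpoint=140)
        assert best_match([far, near], summit=100) is near
        minus = self.mk(900, midpoint=110, strand="-")
        assert best_match([minus, near], summit=100) is near

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            best_match([])


class TestMinus8:
    def test_plus_strand_reads_upstream_base(self, pwm):
        seq = "G" + "A" * 7 + pwm.consensus  # motif starts at 8, midpoint 14
        genome = GenomeSequence({"chrI": seq})
        m = [x for x in scan_pwm(seq, pwm, chrom="chrI") if x.strand == "+"][0]
        assert m.midpoint == 14
        assert annotate_minus8(m, genome).minus8_base == seq[6]

    def test_minus_strand_complements_downstream_base(self, pwm):
        # minus-strand midpoint sits at L-1-mid = 6; its -8 context is the
        # genomic base at 6 + 8 = 14, read complemented
        core = revcomp(pwm.consensus)  # length 13
        seq = core + "AC"
        genome = GenomeSequence({"chrI": seq})
        m = [x for x in scan_pwm(seq, pwm, chrom="chrI") if x.strand == "-"][0]
        assert m.midpoint + 8 == 14
        assert seq[14] == "C"
        assert annotate_minus8(m, genome).minus8_base == "G"


class TestConsensusCounts:
    def test_identical_sites_count_to_n(self, pwm):
        seq = "T" * 10 + pwm.consensus + "T" * 10
        genome = GenomeSequence({"chrI": seq})
        m = [x for x in scan_pwm(seq, pwm, chrom="chrI") if x.strand == "+"][0]
        counts = consensus_counts([m] * 4, genome, flank_up=5, flank_down=5)
        assert counts.sum().sum() == 4 * 11
        mid_col = counts[0]
        assert mid_col[pwm.consensus[pwm.midpoint_index]] == 4

    def test_orientation_normalization(self, pwm, rng):
        flanks = "".join(rng.choice(list(BASES), size=40))
        fwd_seq = flanks[:20] + pwm.consensus + flanks[20:]
        genome = GenomeSequence({"f": fwd_seq, "r": revcomp(fwd_seq)})
        mf = [x for x in scan_pwm(fwd_seq, pwm, chrom="f") if x.strand == "+"][0]
        mr = [x for x in scan_pwm(revcomp(fwd_seq), pwm, chrom="r") if x.strand == "-"][0]
        cf = consensus_counts([mf], genome)
        cr = consensus_counts([mr], genome)
        assert cf.equals(cr)

    def test_constructed_minus1_composition(self, pwm):
        # offset -1 from the midpoint lies inside the motif (position
        # mid-1); vary that base between T and C across ten sites — a
        # single informative-position mismatch still clears the threshold
        mid = pwm.midpoint_index
        genomes, matches = {}, []
        for i, base in enumerate("T" * 7 + "C" * 3):
            motif = pwm.consensus[: mid - 1] + base + pwm.consensus[mid:]
            seq = "A" * 10 + motif + "A" * 10
            chrom = f"chr{i}"
            genomes[chrom] = seq
            matches.append(
                [x for x in scan_pwm(seq, pwm, chrom=chrom) if x.strand == "+"][0]
            )
        genome = GenomeSequence(genomes)
        counts = consensus_counts(matches, genome)
        assert list(counts[-1]) == [0, 3, 0, 7]  # A, C, G, T at -1


class TestPositionEnrichment:
    def test_identical_proportions_p_one(self):
        assert position_enrichment_test([5, 5, 0, 10], [10, 10, 0, 20], "T") == 1.0

    def test_extreme_table_matches_hypergeometric_enumeration(self):
        # group all-T (10), rest all-C (10): p from exhaustive enumeration
        p = position_enrichment_test([0, 0, 0, 10], [0, 10, 0, 0], "T")
        pmf = lambda k: (
            math.comb(10, k) * math.comb(10, 10 - k) / math.comb(20, 10)
        )
        obs = pmf(10)
        expected = sum(pmf(k) for k in range(11) if pmf(k) <= obs + 1e-12)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            position_enrichment_test([0, 0, 0, 0], [1, 1, 1, 1], "A")
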