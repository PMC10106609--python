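import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from loopanchor.io import GenomicInterval
from loopanchor.motif import (
    PWM,
    pwm_from_counts,
    read_counts,
    reverse_complement,
    scan_region,
    score_window,
    uniform_background,
    write_counts_jaspar,
)

from conftest import make_genome

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def uniform_pwm(width):
    return PWM(np.full((width, 4), 0.25), uniform_background())


def informative_pwm(seed=0, width=8):
    rng = np.random.default_rng(seed)
    cons = rng.integers(0, 4, width)
    probs = np.full((width, 4), 0.05)
    probs[np.arange(width), cons] = 0.85
    return PWM(probs, uniform_background())


def brute_force_best(pwm, seq):
    """Exhaustive (offset, strand) argmax with the smaller-start, +-first
    tie-break; the independent oracle for scan_region."""
    best = None
    for off in range(len(seq) - pwm.width + 1):
        window = seq[off : off + pwm.width]
        for strand in "+-":
            s = score_window(pwm, window, strand)
            if best is None or s > best[0]:
                best = (s, off, strand)
    return best


class TestReverseComplement:
    def test_palindrome(self):
        assert reverse_complement("ACGT") == "ACGT"

    def test_hand_example(self):
        assert reverse_complement("AACGTN") == "NACGTT"

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=80))
    def test_involution(self, s):
        assert reverse_complement(reverse_complement(s)) == s

    def test_invalid_characters(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGU")


class TestPwmFromCounts:
    def test_symmetric_row(self):
        pwm = pwm_from_counts(np.array([[1, 1, 1, 1]]), pseudocount=0)
        assert np.allclose(pwm.probs, 0.25)

    def test_hand_arithmetic(self):
        # counts (3,0,0,1), pseudocount 1 -> (4,1,1,2)/8
        pwm = pwm_from_counts(np.array([[3, 0, 0, 1]]), pseudocount=1)
        assert np.allclose(pwm.probs[0], [0.5, 0.125, 0.125, 0.25])

    def test_width_19(self):
        counts = np.ones((19, 4))
        assert pwm_from_counts(counts).width == 19

    def test_all_zero_row_without_pseudocount(self):
        with pytest.raises(ValueError):
            pwm_from_counts(np.zeros((2, 4)), pseudocount=0)

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PWM(np.array([[0.5, 0.2, 0.2, 0.2]]), uniform_background())


class TestScoreWindow:
    def test_uniform_pwm_scores_zero(self):
        pwm = uniform_pwm(5)
        assert score_window(pwm, "ACGTA") == 0.0

    def test_hand_arithmetic_two_positions(self):
        probs = np.array([[0.7, 0.1, 0.1, 0.1],   # A favoured
                          [0.1, 0.1, 0.1, 0.7]])  # T favoured
        pwm = PWM(probs, uniform_background())
        expected = math.log2(0.7 / 0.25) * 2
        assert score_window(pwm, "AT") == pytest.approx(expected)

    @given(st.text(alphabet="ACGT", min_size=7, max_size=7))
    def test_minus_strand_is_revcomp_on_plus(self, w):
        rng = np.random.default_rng(5)
        probs = rng.dirichlet(np.ones(4) * 2, size=7)
        pwm = PWM(probs, uniform_background())
        assert score_window(pwm, w, "-") == pytest.approx(
            score_window(pwm, reverse_complement(w), "+")
        )

    def test_n_scores_minus_infinity(self):
        assert score_window(uniform_pwm(3), "ANG") == float("-inf")

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            score_window(uniform_pwm(3), "ACGT")


class TestScanRegion:
    def test_planted_consensus_recovered(self):
        pwm = informative_pwm(1)
        cons = pwm.consensus()
        rng = np.random.default_rng(2)
        bg = "".join(rng.choice(list("ACGT"), 100))
        seq = bg[:40] + cons + bg[40:]
        genome = make_genome({"chr1": seq})
        hit = scan_region(pwm, genome, GenomicInterval("chr1", 0, len(seq)))
        assert hit.interval.start == 40 and hit.interval.strand == "+"

    def test_agrees_with_brute_force_on_random_regions(self):
        pwm = informative_pwm(3)
        rng = np.random.default_rng(4)
        for trial in range(100):
            n = int(rng.integers(pwm.width, 201))
            seq = "".join(rng.choice(list("ACGT"), n))
            genome = make_genome({"c": seq})
            hit = scan_region(pwm, genome, GenomicInterval("c", 0, n))
            score, off, strand = brute_force_best(pwm, seq)
            assert hit.score == pytest.approx(score)
            assert (hit.interval.start, hit.interval.strand) == (off, strand)

    def test_palindromic_tie_prefers_plus(self):
        # a self-reverse-complementary PWM scores + and - equally everywhere
        probs = np.array([[0.4, 0.1, 0.1, 0.4]] * 4)
        pwm = PWM(probs, uniform_background())
        genome = make_genome({"c": "ATATATAT"})
        hit = scan_region(pwm, genome, GenomicInterval("c", 0, 8))
        assert hit.interval.strand == "+"
        assert hit.interval.start == 0  # smallest start wins the tie

    def test_region_shorter_than_width(self):
        with pytest.raises(ValueError):
            scan_region(uniform_pwm(9), make_genome({"c": "ACGT"}),
                        GenomicInterval("c", 0, 4))

    def test_all_n_region_yields_sentinel(self):
        genome = make_genome({"c": "NNNNNNNN"})
        assert scan_region(uniform_pwm(4), genome,
                           GenomicInterval("c", 0, 8)) is None

    def test_strand_antisymmetry(self):
        # plant the consensus once so the maximum is unique: the mirror-image
        # hit must come back, on the other strand, with the identical score
        pwm = informative_pwm(6)
        rng = np.random.default_rng(7)
        bg = "".join(rng.choice(list("ACGT"), 112))
        seq = bg[:50] + pwm.consensus() + bg[50:]
        fwd = scan_region(pwm, make_genome({"c": seq}),
                          GenomicInterval("c", 0, 120))
        rev = scan_region(pwm, make_genome({"c": reverse_complement(seq)}),
                          GenomicInterval("c", 0, 120))
        assert rev.score == pytest.approx(fwd.score)
        assert rev.interval.start == 120 - fwd.interval.end
        assert rev.interval.strand != fwd.interval.strand

    def test_consensus_monotonicity(self):
        pwm = informative_pwm(8)
        cons = pwm.consensus()
        base_score = score_window(pwm, cons)
        for pos in range(pwm.width):
            probs = pwm.probs.copy()
            b = probs[pos].argmax()
            probs[pos] = (1 - 0.95) / 3
            probs[pos, b] = 0.95  # raise the consensus probability
            boosted = PWM(probs, uniform_background())
            assert score_window(boosted, cons) >= base_score


class TestCountFiles:
    def test_jaspar_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 100, size=(19, 4)).astype(float)
        p = tmp_path / "m.jaspar"
        write_counts_jaspar(counts, p)
        assert np.array_equal(read_counts(p), counts)

    def test_plain_tsv(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("A\tC\tG\tT\n1\t2\t3\t4\n5\t6\t7\t8\n")
        assert np.array_equal(read_counts(p), [[1, 2, 3, 4], [5, 6, 7, 8]])

    def test_bracketless_jaspar(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("A 1 2\nC 3 4\nG 5 6\nT 7 8\n")
        assert np.array_equal(read_counts(p), [[1, 3, 5, 7], [2, 4, 6, 8]])
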