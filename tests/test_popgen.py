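import itertools
import math

import numpy as np
import pytest
from scipy import integrate, special

from conftest import make_alignment, single_site_alignment
from hzscan.popgen import (
    coded_alignment,
    hudson_fst,
    locus_popgen,
    nucleotide_diversity,
    tajima_beta_pvalue,
    tajima_components,
    tajimas_d,
    watterson_theta,
)


def pairwise_loop_pi(aln):
    """Independent oracle: explicit pairwise-difference loop (per-pair deletion)."""
    seqs = [s for _, s in aln.sequences]
    keep = [i for i in range(len(seqs[0])) if all(s[i] != "-" for s in seqs)]
    vals = []
    for s1, s2 in itertools.combinations(seqs, 2):
        cols = [(s1[i], s2[i]) for i in keep if s1[i] != "N" and s2[i] != "N"]
        vals.append(sum(a != b for a, b in cols) / len(cols))
    return sum(vals) / len(vals)


def frequency_form_pi(aln):
    """Independent oracle: pi = sum_s n/(n-1) * (1 - sum p^2) / L (no missing)."""
    seqs = [s for _, s in aln.sequences]
    n, L = len(seqs), len(seqs[0])
    total = 0.0
    for i in range(L):
        col = [s[i] for s in seqs]
        _, counts = np.unique(col, return_counts=True)
        p = counts / n
        total += n / (n - 1) * (1 - (p**2).sum())
    return total / L


class TestPi:
    def test_identical_sequences(self):
        aln = make_alignment(["AAAA"] * 10)
        assert nucleotide_diversity(aln) == 0.0

    def test_single_split_site(self):
        # n=4, L=10, one site split 2/2: 4 differing pairs of 6 -> (4/6)/10
        cols = ["AAAA"] * 9 + ["AACC"]
        aln = make_alignment(cols)
        assert nucleotide_diversity(aln) == pytest.approx(4 / 6 / 10)

    def test_single_pair(self):
        cols = ["AA"] * 99 + ["AC"]
        aln = make_alignment(cols)
        assert nucleotide_diversity(aln) == pytest.approx(0.01)

    def test_matches_pairwise_loop_oracle_with_missing(self, rng):
        bases = rng.choice(list("ACGTN"), size=(8, 40), p=[0.3, 0.3, 0.2, 0.15, 0.05])
        aln = make_alignment(["".join(c) for c in bases.T])
        assert nucleotide_diversity(aln) == pytest.approx(
            pairwise_loop_pi(aln), abs=1e-12)

    def test_matches_frequency_form_without_missing(self, rng):
        for _ in range(20):
            bases = rng.choice(list("ACGT"), size=(6, 25))
            aln = make_alignment(["".join(c) for c in bases.T])
            assert nucleotide_diversity(aln) == pytest.approx(
                frequency_form_pi(aln), abs=1e-9)

    def test_needs_two_haplotypes(self):
        aln = make_alignment(["AAAA", "AACC"])  # 4 haplotypes, 2 columns
        with pytest.raises(ValueError):
            nucleotide_diversity(aln, ["h0"])


class TestWatterson:
    def test_zero_segregating(self):
        assert watterson_theta(0, 10, 100) == 0.0

    def test_harmonic_sum_oracle(self):
        a1 = sum(1 / i for i in range(1, 10))
        assert a1 == pytest.approx(2.828968, abs=1e-6)
        assert watterson_theta(14, 10, 1) == pytest.approx(14 / a1)
        assert watterson_theta(14, 10, 1) == pytest.approx(4.9488, abs=1e-4)

    def test_pair_case(self):
        assert watterson_theta(3, 2, 100) == pytest.approx(0.03)


class TestTajima:
    def test_undefined_for_no_segregation(self):
        aln = make_alignment(["AAAA"] * 5)
        assert math.isnan(locus_popgen(aln, "p").D)

    def test_singleton_excess_is_negative(self):
        # n=10, every segregating site a singleton on the same haplotype
        cols = ["C" + "A" * 9] * 10 + ["A" * 10] * 20
        aln = make_alignment(cols)
        assert tajimas_d(aln).D < 0

    def test_step_by_step_constant_oracle(self):
        # fixed 6-haplotype fixture, verified against raw formula arithmetic
        cols = ["AACCCC", "AAAACC", "ACACAC", "AAAAAC", "AAAAAA" , "CAAAAA"]
        aln = make_alignment(cols)
        tc = tajimas_d(aln)
        n = 6
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        codes = coded_alignment(aln)
        S = sum(1 for col in codes.T if len(set(col)) > 1)
        pi = sum(
            sum(x != y for x, y in zip(codes[i], codes[j]))
            for i, j in itertools.combinations(range(n), 2)
        ) / math.comb(n, 2)
        D = (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        assert tc.S == S
        assert tc.pi_total == pytest.approx(pi, abs=1e-12)
        assert tc.D == pytest.approx(D, abs=1e-12)
        assert tc.a1 == pytest.approx(a1, abs=1e-12)
        assert tc.e1 > 0 and tc.e2 > 0
        assert tc.D_min < 0 < tc.D_max

    def test_sign_matches_pi_minus_theta(self, rng):
        for _ in range(10):
            bases = rng.choice(["A", "C"], size=(8, 50), p=[0.85, 0.15])
            aln = make_alignment(["".join(c) for c in bases.T])
            r = locus_popgen(aln, "p")
            if r.S == 0 or math.isnan(r.D):
                continue
            assert np.sign(r.D) == np.sign(r.pi_per_bp - r.theta_w_per_bp)


class TestBetaPvalue:
    def test_central_value_near_one(self):
        tc = tajima_components(10, 14, 14 / sum(1 / i for i in range(1, 10)))
        assert abs(tc.D) < 1e-6
        assert tc.p > 0.85

    def test_extreme_value_significant(self):
        tc = tajima_components(10, 14, 0.0)
        tc.D = tc.D_max - 1e-6
        assert tajima_beta_pvalue(tc) < 0.05
        tc.D = tc.D_min + 1e-6
        assert tajima_beta_pvalue(tc) < 0.05

    def test_matches_quadrature_oracle(self):
        # independent oracle: numerically integrate the same beta density
        tc = tajima_components(12, 9, 5.0)
        a, b = tc.D_min, tc.D_max
        total = -a * b - 1
        u = -a / (b - a)
        p_shape, q_shape = u * total, (1 - u) * total

        def density(x):
            z = (x - a) / (b - a)
            lognum = (p_shape - 1) * math.log(z) + (q_shape - 1) * math.log(1 - z)
            return math.exp(lognum - special.betaln(p_shape, q_shape)) / (b - a)

        F, _ = integrate.quad(density, a, tc.D, limit=200)
        expected = 2 * min(F, 1 - F)
        assert tc.p == pytest.approx(expected, abs=1e-6)

    def test_neutral_coalescent_rejection_rate(self):
        # beta approximation is approximate: rejection in [0.02, 0.09] at alpha=.05
        from hzscan.synth import haplotype_matrix_stats, simulate_coalescent_sample
        rng = np.random.default_rng(77)
        rejections = total = 0
        for _ in range(2000):
            m = simulate_coalescent_sample(10, 5.0, rng)
            n, S, pi = haplotype_matrix_stats(m)
            if S == 0:
                continue
            total += 1
            rejections += tajima_components(n, S, pi).p < 0.05
        assert 0.02 <= rejections / total <= 0.09


class TestHudsonFst:
    def test_identical_populations_near_zero(self):
        # with identical multisets the estimate is slightly negative, not 0:
        # Hw excludes self-pairs while Hb does not (Hw = n/(n-1) * Hb), a
        # known small-sample property of the unclamped estimator
        aln, a, b = single_site_alignment("AACC", "AACC")
        rec = hudson_fst(aln, a, b)
        n = 4
        assert rec.fst == pytest.approx(1 - n / (n - 1), abs=1e-12)
        # the bias vanishes with sample size
        aln2, a2, b2 = single_site_alignment("A" * 20 + "C" * 20,
                                             "A" * 20 + "C" * 20)
        assert abs(hudson_fst(aln2, a2, b2).fst) < 0.03

    def test_fixed_difference_is_one(self):
        aln, a, b = single_site_alignment("AAAA", "CCCC")
        rec = hudson_fst(aln, a, b)
        assert rec.Hw == 0.0
        assert rec.fst == 1.0

    def test_hand_derived_single_site(self):
        aln, a, b = single_site_alignment("A" * 9 + "C", "A" + "C" * 9)
        rec = hudson_fst(aln, a, b)
        assert rec.Hw == pytest.approx(0.2)
        assert rec.Hb == pytest.approx(0.82)
        assert rec.fst == pytest.approx(0.756098, abs=1e-6)

    def test_invariant_to_relabeling_and_duplication(self, rng):
        bases = rng.choice(["A", "G"], size=(12, 30))
        aln = make_alignment(["".join(c) for c in bases.T])
        a, b = aln.names[:6], aln.names[6:]
        f1 = hudson_fst(aln, a, b).fst
        f2 = hudson_fst(aln, b, a).fst
        assert f1 == pytest.approx(f2, abs=1e-12)
        # duplicating every haplotype changes only Hw, by the exact factor
        # (2n-2)/(2n-1) (self-copy pairs enter the within-population mean);
        # Hb and hence the estimate's large-n limit are untouched
        rec = hudson_fst(aln, a, b)
        doubled = make_alignment(["".join(c) + "".join(c) for c in bases.T],
                                 prefix="d")
        da = doubled.names[:6] + doubled.names[12:18]
        db = doubled.names[6:12] + doubled.names[18:]
        rec2 = hudson_fst(doubled, da, db)
        n = 6
        assert rec2.Hb == pytest.approx(rec.Hb, abs=1e-12)
        assert rec2.Hw == pytest.approx(rec.Hw * (2 * n - 2) / (2 * n - 1),
                                        abs=1e-12)

    def test_small_population_errors(self):
        aln, a, b = single_site_alignment("AA", "C")
        with pytest.raises(ValueError):
            hudson_fst(aln, a, b)
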