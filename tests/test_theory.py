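"""Closed forms: run-length law, permutation counts, probability vectors,
optimal offsets, conservation — each certified against its brute-force
oracle on a small grid, plus the structural invariants."""

import math
from fractions import Fraction

import pytest

from kselect import theory
from kselect import oracles
from kselect.selectors import MethodSpec


# ---------------------------------------------------------------------------
# run-length distribution of unmutated covering k-mers
# ---------------------------------------------------------------------------

class TestRunLength:
    def test_no_mutation_is_point_mass_at_k(self):
        d = theory.run_length_distribution(0.0, 8)
        assert d.prob(8) == 1 and sum(d.probs) == 1

    def test_certain_mutation_is_point_mass_at_zero(self):
        d = theory.run_length_distribution(1.0, 8)
        assert d.prob(0) == 1

    def test_hand_enumerated_k2_half(self):
        # 3 trials at theta=1/2: exactly the runs SSF and FSS give alpha=1,
        # SSS gives alpha=2
        d = theory.run_length_distribution(Fraction(1, 2), 2)
        assert d.prob(1) == Fraction(1, 4)
        assert d.prob(2) == Fraction(1, 8)

    @pytest.mark.parametrize("theta", [0.1, 0.3, 0.5])
    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5, 6])
    def test_matches_exhaustive_enumeration(self, theta, k):
        got = theory.run_length_distribution(theta, k).probs
        want = oracles.enumerate_bernoulli_runs(theta, k).probs
        assert max(abs(a - b) for a, b in zip(got, want)) < 1e-12

    @pytest.mark.parametrize("k", [2, 7, 15, 25])
    def test_normalized_on_theta_grid(self, k):
        for i in range(0, 21):
            d = theory.run_length_distribution(i / 20, k)
            assert abs(sum(d.probs) - 1) < 1e-12
            assert all(p >= -1e-15 for p in d.probs)
            assert abs(d.prob(k) - (1 - i / 20) ** (2 * k - 1)) < 1e-12

    def test_rejects_bad_theta(self):
        with pytest.raises(ValueError):
            theory.run_length_distribution(1.5, 5)


# ---------------------------------------------------------------------------
# syncmer permutation counts
# ---------------------------------------------------------------------------

class TestSyncmerCounts:
    def test_closed_density_entry(self):
        # alpha=1: 2(k-s)! successes out of (k-s+1)! => 2/(k-s+1)
        for k, s in [(15, 11), (10, 7), (6, 5)]:
            assert theory.closed_syncmer_count(1, k, s) == 2 * math.factorial(k - s)
            assert theory.closed_syncmer_probvec(k, s).density == Fraction(2, k - s + 1)

    def test_closed_probvec_15_11_prefix(self):
        pv = theory.closed_syncmer_probvec(15, 11)
        assert pv.entries[:5] == (Fraction(2, 5), Fraction(2, 3), Fraction(6, 7),
                                  Fraction(1), Fraction(1))

    @pytest.mark.parametrize("d", [1, 2, 3])
    @pytest.mark.parametrize("alpha", [1, 2, 3, 4])
    def test_closed_count_matches_enumeration(self, d, alpha):
        got = theory.closed_syncmer_count(alpha, d + 4, 4)
        assert got == oracles.enumerate_syncmer_permutations(alpha, d, "closed")

    def test_open_two_slot_window_is_half(self):
        assert theory.open_syncmer_probvec(8, 7, 1).density == Fraction(1, 2)
        assert theory.open_syncmer_probvec(8, 7, 2).density == Fraction(1, 2)

    def test_open_density_15_11_3(self):
        assert theory.open_syncmer_probvec(15, 11, 3).density == Fraction(1, 5)

    @pytest.mark.parametrize("d", [1, 2, 3, 4])
    def test_open_count_matches_enumeration_all_offsets(self, d):
        for t in range(1, d + 2):
            for alpha in range(1, 5):
                got = theory.open_syncmer_count(alpha, d + 4, 4, t)
                assert got == oracles.enumerate_syncmer_permutations(alpha, d, t)

    def test_open_interior_offset_has_no_window_guarantee(self):
        # for 1 < t < k-s+1 no entry reaches 1 (cf. the homopolymer example)
        for d in (2, 3, 4):
            k, s = d + 6, 6
            for t in range(2, d + 1):
                pv = theory.open_syncmer_probvec(k, s, t)
                assert all(e < 1 for e in pv.entries)

    def test_offset_mirror_symmetry(self):
        for d in range(1, 6):
            k, s = d + 6, 6
            for t in range(1, d + 2):
                a = theory.open_syncmer_probvec(k, s, t).entries
                b = theory.open_syncmer_probvec(k, s, d + 2 - t).entries
                assert a == b

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            theory.closed_syncmer_count(1, 5, 5)
        with pytest.raises(ValueError):
            theory.open_syncmer_count(1, 8, 5, 5)  # t > k-s+1


class TestOptimalOffset:
    def test_middle_slot_is_optimal_exhaustively(self):
        for d in range(1, 6):
            k, s = d + 6, 6
            t_hat, alt = theory.optimal_open_syncmer_offset(k, s)
            assert t_hat == math.ceil((d + 1) / 2)
            for alpha in range(1, 6):
                best = theory.open_syncmer_count(alpha, k, s, t_hat)
                for t in range(1, d + 2):
                    assert best >= theory.open_syncmer_count(alpha, k, s, t)
                if alt is not None:
                    assert best == theory.open_syncmer_count(alpha, k, s, alt)

    def test_known_offsets(self):
        assert theory.optimal_open_syncmer_offset(15, 11)[0] == 3
        assert theory.optimal_open_syncmer_offset(8, 7) == (1, 2)  # both optimal
        assert theory.optimal_open_syncmer_offset(17, 14) == (2, 3)


# ---------------------------------------------------------------------------
# minimizer permutation counts
# ---------------------------------------------------------------------------

class TestMinimizer:
    def test_zero_when_window_exceeds_n(self):
        assert theory.minimizer_count(3, 5, 1, 2) == 0

    def test_density_from_count(self):
        for w in (2, 3, 4):
            n = 2 * (w - 1) + 1
            got = Fraction(theory.minimizer_count(n, w, 1, w), math.factorial(n))
            assert got == Fraction(2, w + 1)

    @pytest.mark.parametrize("n", range(1, 9))
    def test_count_matches_enumeration(self, n):
        for w in range(1, n + 1):
            for alpha in range(1, n + 1):
                for p in range(1, n - alpha + 2):
                    got = theory.minimizer_count(n, w, alpha, p)
                    want = oracles.enumerate_minimizer_permutations(n, w, alpha, p)
                    assert got == want, (n, w, alpha, p)

    @pytest.mark.parametrize("w", range(1, 13))
    def test_recurrence_agrees_with_simplified_closed_form(self, w):
        # minimizer_probvec raises ArithmeticError on any disagreement
        pv = theory.minimizer_probvec(w, k=max(w, 2))
        assert pv.density == Fraction(2, w + 1)
        assert pv.entries[min(w, pv.k) - 1] == 1 if w <= pv.k else True

    def test_w1_selects_everything(self):
        assert theory.minimizer_probvec(1, 6).entries == (Fraction(1),) * 6


# ---------------------------------------------------------------------------
# (a,b,n)-words
# ---------------------------------------------------------------------------

class TestAbnWords:
    def test_densities(self):
        assert theory.abn_words_probvec(6, 2).density == Fraction(9, 64)
        assert theory.abn_words_probvec(6, 3).density == Fraction(27, 256)

    def test_n0_collapses_to_geometric(self):
        pv = theory.abn_words_probvec(8, 0)
        for a in range(1, 9):
            assert pv.entry(a) == 1 - Fraction(3, 4) ** a

    @pytest.mark.parametrize("n", [0, 1, 2, 3])
    def test_matches_string_enumeration(self, n):
        alpha_max = min(6, 10 - n)
        pv = theory.abn_words_probvec(alpha_max, n)
        for a in range(1, alpha_max + 1):
            assert pv.entry(a) == oracles.enumerate_word_method_strings(n, a)


# ---------------------------------------------------------------------------
# union bound, structural invariants, conservation
# ---------------------------------------------------------------------------

ALL_CLOSED_FORM_SPECS = [
    MethodSpec("minimizer", k=17, w=7),
    MethodSpec("closed_syncmer", k=17, s=10),
    MethodSpec("open_syncmer", k=17, s=14, t=2),
    MethodSpec("open_syncmer", k=15, s=11, t=3),
    MethodSpec("abn_words", k=17, n=2),
]


class TestUnionBound:
    def test_pattern(self):
        ub = theory.union_upper_bound(Fraction(1, 4), 17)
        assert ub.entries[:4] == (Fraction(1, 4), Fraction(1, 2),
                                  Fraction(3, 4), Fraction(1))
        assert all(e == 1 for e in ub.entries[3:])
        assert all(e == 1 for e in theory.union_upper_bound(1, 5).entries)

    @pytest.mark.parametrize("spec", ALL_CLOSED_FORM_SPECS,
                             ids=lambda s: s.describe())
    def test_every_probvec_monotone_and_below_ub(self, spec):
        pv = theory.probability_vector(spec)
        assert pv.is_monotone()
        ub = theory.union_upper_bound(pv.density, pv.k)
        assert all(e <= u for e, u in zip(pv.entries, ub.entries))


class TestConservation:
    def test_theta_zero_is_full_window_probability(self, ):
        pv = theory.closed_syncmer_probvec(15, 11)
        assert theory.conservation(pv, 0.0).value == pytest.approx(float(pv.entry(15)))

    def test_theta_one_is_zero(self):
        pv = theory.open_syncmer_probvec(15, 11, 3)
        assert theory.conservation(pv, 1.0).value == 0

    @pytest.mark.parametrize("spec", ALL_CLOSED_FORM_SPECS,
                             ids=lambda s: s.describe())
    def test_monotone_nonincreasing_in_theta(self, spec):
        pv = theory.probability_vector(spec)
        vals = [theory.conservation(pv, th).value for th in
                [i / 50 for i in range(51)]]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_mode_tracks_locality(self):
        pv = theory.minimizer_probvec(7, 17)
        c = theory.conservation(pv, 0.1, method=ALL_CLOSED_FORM_SPECS[0])
        assert c.mode == "upper_bound"
        c2 = theory.conservation(theory.abn_words_probvec(17, 2), 0.1,
                                 method=ALL_CLOSED_FORM_SPECS[-1])
        assert c2.mode == "exact"

    def test_length_mismatch_rejected(self):
        pv = theory.abn_words_probvec(6, 1)
        # probvec carries its own k; a theta outside [0,1] is the domain error
        with pytest.raises(ValueError):
            theory.conservation(pv, -0.2)


class TestDensities:
    def test_table_values(self):
        assert theory.theoretical_density(MethodSpec("minimizer", k=15, w=9)) == Fraction(1, 5)
        assert theory.theoretical_density(MethodSpec("open_syncmer", k=15, s=11, t=3)) == Fraction(1, 5)
        assert theory.theoretical_density(MethodSpec("closed_syncmer", k=15, s=11)) == Fraction(2, 5)
        assert theory.theoretical_density(MethodSpec("abn_words", k=15, n=3)) == Fraction(27, 256)
        ws = frozenset({"AC", "GT", "TT"})
        assert theory.theoretical_density(MethodSpec("word_set", k=15, words=ws)) == Fraction(3, 16)

    def test_miniception_is_empirical_only(self):
        with pytest.raises(theory.EmpiricalOnlyDensity):
            theory.theoretical_density(MethodSpec("miniception", k=15, w=9))
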