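"""Brute-force reference computations.

Everything here works directly from the definitions — exhaustive enumeration
of permutations, Bernoulli configurations or strings — and shares no code
with the closed forms in :mod:`kselect.theory`.  The test suite certifies
every closed form against these references on a small-parameter grid before
it is trusted at scale; the ``verify`` CLI subcommand re-runs the full grid.

All enumerations refuse inputs past a hard size bound rather than grinding.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from itertools import permutations, product

from .selectors import MethodSpec, SelectionResult

_PERM_BOUND = 9          # enumerate S_n only for n <= 9 (362 880 perms)
_BERNOULLI_BOUND = 6     # 2^(2k-1) configurations, k <= 6
_STRING_BOUND = 10       # 4^L strings, L <= 10


@dataclass(frozen=True)
class OracleReport:
    formula_name: str
    parameter_set: tuple
    formula_value: object
    oracle_value: object

    @property
    def abs_diff(self):
        f, o = self.formula_value, self.oracle_value
        if isinstance(f, tuple):
            return max(abs(a - b) for a, b in zip(f, o))
        return abs(f - o)

    @property
    def ok(self) -> bool:
        return self.formula_value == self.oracle_value

    def row(self) -> str:
        mark = "ok" if self.ok else "FAIL"
        return (f"{self.formula_name}\t{self.parameter_set}\t"
                f"{self.formula_value}\t{self.oracle_value}\t{mark}")


def _check_perm_bound(n: int):
    if n > _PERM_BOUND:
        raise ValueError(f"permutation enumeration limited to n <= {_PERM_BOUND}, got {n}")


def enumerate_syncmer_permutations(alpha: int, k_minus_s: int,
                                   t_or_closed) -> int:
    """Count permutations of the k-s+alpha s-mer ranks under which at least
    one of the alpha windows of k-s+1 slots has its minimum at the required
    slot: 1-indexed slot t for open syncmers, or the first/last slot when
    ``t_or_closed == 'closed'``.
    """
    n = k_minus_s + alpha
    _check_perm_bound(n)
    wlen = k_minus_s + 1
    closed = t_or_closed == "closed"
    if not closed:
        tau = int(t_or_closed) - 1
        if not 0 <= tau <= k_minus_s:
            raise ValueError("t out of range")
    count = 0
    for sigma in permutations(range(n)):
        for i in range(alpha):
            window = sigma[i : i + wlen]
            j = window.index(min(window))
            if closed:
                if j == 0 or j == wlen - 1:
                    count += 1
                    break
            elif j == tau:
                count += 1
                break
    return count


@lru_cache(maxsize=None)
def _minimizer_hit_masks(n: int, w: int) -> tuple:
    """For each permutation of S_n, a bitmask of the slots (0-indexed) that
    are the leftmost minimum of some w-window."""
    masks = []
    for sigma in permutations(range(n)):
        mask = 0
        for i in range(n - w + 1):
            window = sigma[i : i + w]
            mask |= 1 << (i + window.index(min(window)))
        masks.append(mask)
    return tuple(masks)


def enumerate_minimizer_permutations(n: int, w: int, alpha: int, p: int) -> int:
    """Count permutations of S_n for which some w-window has its minimum in
    slots p..p+alpha-1 (1-indexed)."""
    _check_perm_bound(n)
    if p + alpha - 1 > n:
        raise ValueError("need p+alpha-1 <= n")
    if w > n:
        return 0
    target = ((1 << alpha) - 1) << (p - 1)
    return sum(1 for m in _minimizer_hit_masks(n, w) if m & target)


def enumerate_bernoulli_runs(theta, k: int):
    """Exact distribution of alpha = max(0, L-k+1), L the longest success
    run among 2k-1 Bernoulli(1-theta) trials, by summing all 2^(2k-1)
    configuration probabilities.  Exact rationals when theta is a Fraction.
    """
    from .theory import RunLengthDist

    if k > _BERNOULLI_BOUND:
        raise ValueError(f"Bernoulli enumeration limited to k <= {_BERNOULLI_BOUND}")
    m = 2 * k - 1
    q = 1 - theta
    probs = [theta * 0] * (k + 1)
    for bits in range(1 << m):
        longest = run = 0
        for j in range(m):
            if bits >> j & 1:  # success (unmutated)
                run += 1
                longest = max(longest, run)
            else:
                run = 0
        alpha = max(0, longest - k + 1)
        n_succ = bits.bit_count()
        probs[alpha] += q ** n_succ * theta ** (m - n_succ)
    return RunLengthDist(k, float(theta), tuple(probs))


def enumerate_word_method_strings(n: int, alpha: int) -> Fraction:
    """Probability, by exhausting all 4^(alpha+n) strings, that among alpha
    consecutive k-mers at least one starts with an (a,b,n)-word ('A' then n
    non-'A' letters).  Only the first alpha+n characters can matter."""
    L = alpha + n
    if L > _STRING_BOUND:
        raise ValueError(f"string enumeration limited to length <= {_STRING_BOUND}")
    hits = 0
    for s in product(range(4), repeat=L):
        for j in range(alpha):
            if s[j] == 0 and all(s[j + 1 + i] != 0 for i in range(n)):
                hits += 1
                break
    return Fraction(hits, 4 ** L)


def enumerate_word_method_probvec(n: int, alpha_max: int) -> list[Fraction]:
    return [enumerate_word_method_strings(n, a) for a in range(1, alpha_max + 1)]


def window_scan_conservation(S: str, S_mut: str, spec: MethodSpec) -> Fraction:
    """Exact conserved-base fraction by direct construction: run the method
    on both strings, intersect the (k-mer, position) sets, and count bases
    covered by an intersected k-mer.  Deliberately naive — a recount
    independent of the simulation module's vectorized bookkeeping."""
    if len(S) != len(S_mut):
        raise ValueError("strings must have equal length")
    k = spec.k
    sel1 = {(r.kmer, r.position) for r in spec.select(S).selected}
    sel2 = {(r.kmer, r.position) for r in spec.select(S_mut).selected}
    conserved: set[int] = set()
    for kmer, j in sel1 & sel2:
        conserved.update(range(j, j + k))
    return Fraction(len(conserved), len(S))


def verify_all(report: bool = False) -> list[OracleReport]:
    """Run the full small-parameter certification grid for every closed form.

    Returns one OracleReport per tested tuple; any ``ok == False`` entry is
    a transcription bug in the closed forms.
    """
    from . import theory

    reports: list[OracleReport] = []

    # run-length law vs Bernoulli enumeration (exact rationals)
    for k in range(1, 7):
        for th in (Fraction(1, 10), Fraction(3, 10), Fraction(1, 2)):
            got = theory.run_length_distribution(th, k).probs
            want = enumerate_bernoulli_runs(th, k).probs
            reports.append(OracleReport("run_length_distribution", (float(th), k),
                                        tuple(got), tuple(want)))

    # closed syncmer counts
    for d in range(1, 5):
        for alpha in range(1, 5):
            got = theory.closed_syncmer_count(alpha, d + 2, 2)
            want = enumerate_syncmer_permutations(alpha, d, "closed")
            reports.append(OracleReport("closed_syncmer_count", (alpha, d),
                                        got, want))

    # open syncmer counts, every offset
    for d in range(1, 5):
        for t in range(1, d + 2):
            for alpha in range(1, 5):
                got = theory.open_syncmer_count(alpha, d + 2, 2, t)
                want = enumerate_syncmer_permutations(alpha, d, t)
                reports.append(OracleReport("open_syncmer_count", (alpha, d, t),
                                            got, want))

    # minimizer permutation counts
    for n in range(1, 9):
        for w in range(1, n + 1):
            for alpha in range(1, n + 1):
                for p in range(1, n - alpha + 2):
                    got = theory.minimizer_count(n, w, alpha, p)
                    want = enumerate_minimizer_permutations(n, w, alpha, p)
                    reports.append(OracleReport("minimizer_count",
                                                (n, w, alpha, p), got, want))

    # (a,b,n)-words probabilities
    for n in range(4):
        alpha_max = min(6, _STRING_BOUND - n)
        got_vec = theory.abn_words_probvec(alpha_max, n).entries
        want_vec = enumerate_word_method_probvec(n, alpha_max)
        for a in range(alpha_max):
            reports.append(OracleReport("abn_words_probvec", (n, a + 1),
                                        got_vec[a], want_vec[a]))

    if report:
        for r in reports:
            print(r.row())
    return reports
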