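"""Exact spread and conservation theory for local k-mer selection.

The central object is the *probability vector* of a method f,

    Pr(f) = [Pr(f,1), ..., Pr(f,k)],

where Pr(f,alpha) is the probability that at least one of alpha consecutive
k-mers of a long i.i.d.-uniform string is selected.  Pr(f,1) is the density;
the growth of the vector measures how spread out selections are (disjoint
selection events grow fastest, clumped ones slowest), with the union bound

    Pr(f,alpha) <= UB(d)[alpha] = min(1, alpha * d).

Under per-base substitution at rate theta (mutant letter uniform over the
other three), the number alpha(theta,k) of unmutated k-mers covering a fixed
base equals max(0, L - k + 1) for L the longest success run in 2k-1
Bernoulli(1-theta) trials, and the expected fraction of bases covered by
k-mers selected identically in both copies (the *conservation*) satisfies

    Cons(f,theta,k) = Pr(f) . Pr(alpha(theta,k))      (equality, 1-local f)
    Cons(f,theta,k) <= Pr(f) . Pr(alpha(theta,k))     (w-local f)

All permutation counts below use exact integer arithmetic and all closed-form
probabilities are exact rationals; they assume distinct s-mers/k-mers within
a window, which holds for random strings up to an O((k-s+alpha)^2 / 4^s)
collision term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Optional, Sequence, Union

from .selectors import MethodSpec

Number = Union[Fraction, float]


# ---------------------------------------------------------------------------
# probability vectors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbabilityVector:
    """Pr(f,alpha) for alpha = 1..k; ``entries[a-1]`` is Pr(f,a).

    exactness: 'exact_rational' (closed form), 'float', or 'empirical'.
    """

    k: int
    entries: tuple
    exactness: str = "exact_rational"

    def __post_init__(self):
        if len(self.entries) != self.k:
            raise ValueError("need exactly k entries")

    def entry(self, alpha: int) -> Number:
        if not 1 <= alpha <= self.k:
            raise ValueError(f"alpha must be in 1..{self.k}")
        return self.entries[alpha - 1]

    @property
    def density(self) -> Number:
        return self.entries[0]

    def as_floats(self) -> list[float]:
        return [float(e) for e in self.entries]

    def is_monotone(self) -> bool:
        return all(b >= a for a, b in zip(self.entries, self.entries[1:]))


def union_upper_bound(d: Number, k: int) -> ProbabilityVector:
    """UB(d): the union-bound ceiling min(1, alpha*d) on any probability
    vector of density d."""
    if not 0 < d <= 1:
        raise ValueError("density must be in (0, 1]")
    one = Fraction(1) if isinstance(d, Fraction) else 1.0
    return ProbabilityVector(k, tuple(min(one, a * d) for a in range(1, k + 1)),
                             "exact_rational" if isinstance(d, Fraction) else "float")


# ---------------------------------------------------------------------------
# run-length distribution of unmutated covering k-mers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunLengthDist:
    """Distribution of alpha(theta,k) over alpha = 0..k; ``probs[a]`` is
    Pr(alpha = a)."""

    k: int
    theta: float
    probs: tuple

    def prob(self, alpha: int) -> Number:
        return self.probs[alpha]

    def positive_part(self) -> tuple:
        """Pr(alpha=1..k) — the vector conservation dots against."""
        return self.probs[1:]


def run_length_distribution(theta: Number, k: int) -> RunLengthDist:
    """Exact law of the number of unmutated k-mers covering a base.

    For beta in 0..k-2:  Pr(alpha = beta+1) =
    (2 + theta*(k-beta-2)) * (1-theta)^(k+beta) * theta, and
    Pr(alpha = k) = (1-theta)^(2k-1); Pr(alpha = 0) is the complement.
    """
    if not 0 <= theta <= 1:
        raise ValueError("theta must lie in [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    q = 1 - theta
    probs: list[Number] = [0] * (k + 1)
    for beta in range(k - 1):
        probs[beta + 1] = (2 + theta * (k - beta - 2)) * q ** (k + beta) * theta
    probs[k] = q ** (2 * k - 1)
    probs[0] = 1 - sum(probs[1:])
    return RunLengthDist(k, float(theta), tuple(probs))


# ---------------------------------------------------------------------------
# closed syncmers: Pr(f,alpha) = CS(alpha,k,s) / (k-s+alpha)!
# ---------------------------------------------------------------------------

def closed_syncmer_count(alpha: int, k: int, s: int) -> int:
    """Number of permutations of k-s+alpha s-mer ranks under which at least
    one of alpha consecutive k-mers is a closed syncmer: 2*alpha*(k-s+alpha-1)!
    for alpha <= k-s, saturating at (k-s+alpha)! beyond (window guarantee)."""
    _check_syncmer(alpha, k, s)
    if alpha <= k - s:
        return 2 * alpha * math.factorial(k - s + alpha - 1)
    return math.factorial(k - s + alpha)


def closed_syncmer_probvec(k: int, s: int) -> ProbabilityVector:
    _check_syncmer(1, k, s)
    entries = tuple(min(Fraction(1), Fraction(2 * a, k - s + a))
                    for a in range(1, k + 1))
    return ProbabilityVector(k, entries)


def _check_syncmer(alpha: int, k: int, s: int):
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    if not 1 <= s < k:
        raise ValueError("need 1 <= s < k")


# ---------------------------------------------------------------------------
# open syncmers: recurrence for OS(alpha,k,s,t)
# ---------------------------------------------------------------------------

def open_syncmer_count(alpha: int, k: int, s: int, t: int) -> int:
    """Number of permutations of k-s+alpha s-mer ranks under which at least
    one of alpha consecutive k-mers is an open syncmer with offset t.

    Recurrence (tau = t-1, l1 = tau, l2 = k-s-tau):
        OS(alpha) = alpha*(k-s+alpha-1)! + R(l1) + R(l2)
        R(l) = sum_{beta=1}^{l} falling(k-s+alpha-1, beta-1) * OS(alpha-beta)
    with OS(alpha-beta) = 0 once beta >= alpha.
    """
    _check_syncmer(alpha, k, s)
    if not 1 <= t <= k - s + 1:
        raise ValueError("need 1 <= t <= k-s+1")
    return _os_count(alpha, k - s, t - 1)


@lru_cache(maxsize=None)
def _os_count(alpha: int, d: int, tau: int) -> int:
    # d = k - s; windows have d+1 slots, min required at 0-indexed slot tau
    if alpha <= 0:
        return 0
    total = alpha * math.factorial(d + alpha - 1)
    for ell in (tau, d - tau):
        for beta in range(1, ell + 1):
            if beta >= alpha:
                break
            total += _falling(d + alpha - 1, beta - 1) * _os_count(alpha - beta, d, tau)
    return total


def _falling(x: int, m: int) -> int:
    out = 1
    for i in range(m):
        out *= x - i
    return out


def open_syncmer_probvec(k: int, s: int, t: int) -> ProbabilityVector:
    entries = tuple(
        Fraction(open_syncmer_count(a, k, s, t), math.factorial(k - s + a))
        for a in range(1, k + 1))
    return ProbabilityVector(k, entries)


def optimal_open_syncmer_offset(k: int, s: int) -> tuple[int, Optional[int]]:
    """The conservation-optimal offset t_hat = ceil((k-s+1)/2); when k-s+1
    is even the mirror k-s+2-t_hat is equally optimal and returned second."""
    _check_syncmer(1, k, s)
    wlen = k - s + 1
    t_hat = (wlen + 1) // 2
    alt = k - s + 2 - t_hat
    return t_hat, (alt if alt != t_hat else None)


# ---------------------------------------------------------------------------
# random minimizers
# ---------------------------------------------------------------------------

def minimizer_count(n: int, w: int, alpha: int, p: int) -> int:
    """Number of permutations of S_n for which some w-window has its minimum
    in slots p..p+alpha-1 (1-indexed).

    M(n,w,alpha,p) = alpha*(n-1)! + R~(l1) + R~(l2) for w <= n (0 for w > n),
    l1 = p-1, l2 = n-(p+alpha-1);
    R~(l) = sum_{beta=1}^{l} M(n-beta, w, alpha, l-beta+1) * falling(n-1, beta-1).
    """
    if alpha < 1 or p < 1 or p + alpha - 1 > n:
        raise ValueError("need alpha >= 1, p >= 1 and p+alpha-1 <= n")
    if w < 1:
        raise ValueError("need w >= 1")
    return _mini_count(n, w, alpha, p)


@lru_cache(maxsize=None)
def _mini_count(n: int, w: int, alpha: int, p: int) -> int:
    if w > n:
        return 0
    total = alpha * math.factorial(n - 1)
    for ell in (p - 1, n - (p + alpha - 1)):
        for beta in range(1, ell + 1):
            total += _mini_count(n - beta, w, alpha, ell - beta + 1) * _falling(n - 1, beta - 1)
    return total


def minimizer_probvec(w: int, k: int) -> ProbabilityVector:
    """Probability vector of a random minimizer: the simplified closed form
    1 - Pr(f,alpha) = (w-alpha+1)(w-alpha) / ((w+1)w) for alpha <= w, 1
    beyond, cross-checked against the permutation-count recurrence at
    (n, alpha, p) = (2(w-1)+alpha, alpha, w)."""
    if w < 1:
        raise ValueError("need w >= 1")
    entries = []
    for a in range(1, k + 1):
        if a >= w:
            pr = Fraction(1)
        else:
            pr = 1 - Fraction((w - a + 1) * (w - a), (w + 1) * w)
        if a <= w:
            n = 2 * (w - 1) + a
            rec = Fraction(minimizer_count(n, w, a, w), math.factorial(n))
            if abs(rec - pr) > Fraction(1, 10**12):
                raise ArithmeticError(
                    f"minimizer recurrence and closed form disagree at "
                    f"(w={w}, alpha={a}): {rec} vs {pr}")
        entries.append(pr)
    return ProbabilityVector(k, tuple(entries))


# ---------------------------------------------------------------------------
# (a,b,n)-words
# ---------------------------------------------------------------------------

def abn_words_probvec(k: int, n: int) -> ProbabilityVector:
    """Probability vector of the (a,b,n)-words rule by inclusion-exclusion
    over disjoint word placements:

    Pr(f,alpha) = sum_{i>=1} (-1)^{i+1} * 3^{n i} / 4^{i(n+1)}
                  * C(alpha - n(i-1), i),  C(x, i) = 0 for x < 0.
    """
    if n < 0:
        raise ValueError("need n >= 0")
    entries = []
    for alpha in range(1, k + 1):
        total = Fraction(0)
        for i in range(1, alpha + 1):
            top = alpha - n * (i - 1)
            c = math.comb(top, i) if top >= 0 else 0
            if c == 0:
                continue
            total += (-1) ** (i + 1) * Fraction(3 ** (n * i), 4 ** (i * (n + 1))) * c
        entries.append(total)
    return ProbabilityVector(k, tuple(entries))


# ---------------------------------------------------------------------------
# densities and conservation
# ---------------------------------------------------------------------------

class EmpiricalOnlyDensity(ValueError):
    """Raised for methods whose density has no closed form (miniception)."""


def theoretical_density(spec: MethodSpec) -> Fraction:
    """Long-string density of a method, exact up to the s-mer/k-mer
    collision term."""
    m = spec.method_name
    if m == "minimizer":
        return Fraction(2, spec.w + 1)
    if m == "open_syncmer":
        return Fraction(1, spec.k - spec.s + 1)
    if m == "closed_syncmer":
        return Fraction(2, spec.k - spec.s + 1)
    if m == "abn_words":
        return Fraction(3 ** spec.n, 4 ** (spec.n + 1))
    if m == "word_set":
        if not spec.words:
            return Fraction(0)
        ell = len(next(iter(spec.words)))
        return Fraction(len(spec.words), 4 ** ell)
    raise EmpiricalOnlyDensity(
        f"{m} has no closed-form density; estimate it empirically")


def probability_vector(spec: MethodSpec) -> ProbabilityVector:
    """Closed-form probability vector for any method that has one."""
    m = spec.method_name
    if m == "minimizer":
        return minimizer_probvec(spec.w, spec.k)
    if m == "closed_syncmer":
        return closed_syncmer_probvec(spec.k, spec.s)
    if m == "open_syncmer":
        return open_syncmer_probvec(spec.k, spec.s, spec.t)
    if m == "abn_words":
        return abn_words_probvec(spec.k, spec.n)
    raise ValueError(f"no closed-form probability vector for {m}")


@dataclass(frozen=True)
class ConservationValue:
    """Cons(f,theta,k): exact for 1-local methods, an upper bound for
    w-local ones (the context-dependency gap)."""

    theta: float
    k: int
    value: float
    mode: str  # 'exact' | 'upper_bound'
    method: Optional[MethodSpec] = None

    def __float__(self) -> float:
        return self.value


def conservation(probvec: ProbabilityVector, theta: Number,
                 one_local: bool = True,
                 method: Optional[MethodSpec] = None) -> ConservationValue:
    """Dot the probability vector against the positive part of the
    run-length law: sum_a Pr(f,a) * Pr(alpha(theta,k) = a)."""
    if method is not None:
        one_local = method.locality == 1
    rld = run_length_distribution(theta, probvec.k)
    val = math.fsum(float(p) * float(q)
                    for p, q in zip(probvec.entries, rld.positive_part()))
    return ConservationValue(float(theta), probvec.k, val,
                             "exact" if one_local else "upper_bound", method)


def conservation_upper_bound(d: Number, theta: Number, k: int) -> float:
    """UB(d) . Pr(alpha(theta,k)): the ceiling no method of density d can
    exceed."""
    return conservation(union_upper_bound(d, k), theta).value


def fraction_of_upper_bound_closed_form(
        probvec: ProbabilityVector, d: Number,
        thetas: Sequence[float]) -> list[tuple[float, float, float, float]]:
    """(theta, Cons, UB-Cons, ratio) along a mutation-rate grid, entirely
    from the closed forms."""
    out = []
    for theta in thetas:
        c = conservation(probvec, theta).value
        ub = conservation_upper_bound(d, theta, probvec.k)
        out.append((float(theta), c, ub, c / ub if ub > 0 else float("nan")))
    return out
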