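"""Monte-Carlo engine: random strings, substitution mutation, and empirical
estimates of density, probability vectors, conservation, gaps and
repetitiveness.

The generative model matches the one the closed forms assume: sequences are
i.i.d.-uniform over {A,C,G,T}, and the mutated copy substitutes each base
independently with probability theta, the replacement drawn uniformly from
the other three letters (no indels).  Replicate estimates are summarized as
mean with a 95% normal-approximation confidence interval.

Seeding: every public routine takes one master seed; replicate r uses the
deterministic sub-seed (seed, r) through numpy's SeedSequence spawning, so
any replicate can be re-run in isolation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._encoding import decode
from .selectors import MethodSpec, SelectionResult, select_positions
from . import theory

_ACGT = np.array(list("ACGT"))


@dataclass(frozen=True)
class EmpiricalEstimate:
    """Replicate mean with a 95% normal-approximation CI."""

    mean: float
    ci_low: float
    ci_high: float
    n_reps: int
    seed: int

    def contains(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high

    @classmethod
    def from_replicates(cls, values: Sequence[float], seed: int) -> "EmpiricalEstimate":
        arr = np.asarray(values, dtype=float)
        m = float(arr.mean())
        half = 1.96 * float(arr.std(ddof=1)) / math.sqrt(len(arr)) if len(arr) > 1 else 0.0
        return cls(m, m - half, m + half, len(arr), seed)


@dataclass(frozen=True)
class MutatedPair:
    """A string and its substitution-mutated copy."""

    original: str
    mutated: str
    theta: float
    seed: int

    @property
    def mismatch_fraction(self) -> float:
        a = np.frombuffer(self.original.encode(), dtype=np.uint8)
        b = np.frombuffer(self.mutated.encode(), dtype=np.uint8)
        return float((a != b).mean())


@dataclass(frozen=True)
class RepetitivenessStats:
    """Multiplicity structure of the selected k-mer strings."""

    n_selected: int
    n_unique: int          # selected k-mers occurring exactly once in the selection
    mean_multiplicity: float


def _rng(seed: int, rep: Optional[int] = None) -> np.random.Generator:
    key = (seed,) if rep is None else (seed, rep)
    return np.random.default_rng(np.random.SeedSequence(key))


def random_codes(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def random_string(length: int, seed: int) -> str:
    """An i.i.d.-uniform string over {A,C,G,T}; reproducible from the seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return decode(random_codes(length, _rng(seed)))


def mutate_codes(codes: np.ndarray, theta: float, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Substitution-mutate coded bases; returns (mutated codes, hit mask).
    A hit base moves to one of the other three letters uniformly."""
    hit = rng.random(codes.shape[0]) < theta
    shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.int8)
    out = codes.copy()
    out[hit] = (out[hit] + shift) % 4
    return out, hit


def mutate(S: str, theta: float, seed: int) -> MutatedPair:
    """Per-base substitution at rate theta (mutant uniform over the other
    three letters)."""
    if not 0 <= theta <= 1:
        raise ValueError("theta must lie in [0, 1]")
    from ._encoding import encode
    codes, valid = encode(S)
    if not valid.all():
        raise ValueError("mutation model defined over ACGT strings only")
    out, _ = mutate_codes(codes, theta, _rng(seed))
    return MutatedPair(S, decode(out), theta, seed)


# ---------------------------------------------------------------------------
# empirical estimates
# ---------------------------------------------------------------------------

def _all_valid(length: int) -> np.ndarray:
    return np.ones(length, dtype=bool)


def empirical_density(spec: MethodSpec, length: int = 50_000,
                      n_reps: int = 10, seed: int = 0) -> EmpiricalEstimate:
    """Fraction of interior k-mer positions selected, averaged over
    replicates.  The first and last w+k positions are discarded to avoid
    edge bias."""
    edge = spec.window_span + spec.k
    vals = []
    for r in range(n_reps):
        codes = random_codes(length, _rng(seed, r))
        mask = np.zeros(length - spec.k + 1, dtype=bool)
        mask[select_positions(codes, _all_valid(length), spec)] = True
        interior = mask[edge:-edge]
        vals.append(float(interior.mean()))
    return EmpiricalEstimate.from_replicates(vals, seed)


def empirical_probvec(spec: MethodSpec, length: int = 50_000,
                      n_reps: int = 10, seed: int = 0) -> theory.ProbabilityVector:
    """Empirical Pr(f,alpha), alpha = 1..k: the fraction of interior
    positions i such that at least one of the alpha k-mers starting at
    i..i+alpha-1 is selected."""
    k = spec.k
    edge = spec.window_span + k
    sums = np.zeros(k)
    counts = np.zeros(k)
    for r in range(n_reps):
        codes = random_codes(length, _rng(seed, r))
        mask = np.zeros(length - k + 1, dtype=bool)
        mask[select_positions(codes, _all_valid(length), spec)] = True
        hit = mask.astype(np.int32)
        cs = np.concatenate(([0], np.cumsum(hit)))
        for a in range(1, k + 1):
            anyhit = (cs[a:] - cs[:-a]) > 0  # any selection in [i, i+a)
            interior = anyhit[edge:-edge]
            sums[a - 1] += interior.sum()
            counts[a - 1] += interior.shape[0]
    return theory.ProbabilityVector(k, tuple(sums / counts), "empirical")


def _conserved_fraction(codes: np.ndarray, mut_codes: np.ndarray,
                        hit: np.ndarray, spec: MethodSpec,
                        edge: int = 0) -> float:
    """Conserved-base fraction for one replicate: bases covered by a k-mer
    selected at the same position in both copies with an identical string
    (i.e. unmutated).  ``edge`` bases at each end are excluded from the
    denominator (0 = the raw |B|/|S|)."""
    length = codes.shape[0]
    k = spec.k
    valid = _all_valid(length)
    m1 = np.zeros(length - k + 1, dtype=bool)
    m1[select_positions(codes, valid, spec)] = True
    m2 = np.zeros(length - k + 1, dtype=bool)
    m2[select_positions(mut_codes, valid, spec)] = True
    # k-mer unmutated <=> no hit base inside [j, j+k)
    cs = np.concatenate(([0], np.cumsum(hit.astype(np.int32))))
    unmut = (cs[k:] - cs[:-k]) == 0
    matched = m1 & m2 & unmut
    # base i is conserved if some matched k-mer start lies in [i-k+1, i]
    ms = np.concatenate(([0], np.cumsum(matched.astype(np.int64))))
    starts = np.arange(length) - k + 1
    lo = np.clip(starts, 0, None)
    hi = np.minimum(np.arange(length), length - k) + 1
    covered = (ms[np.clip(hi, 0, len(ms) - 1)] - ms[lo]) > 0
    if edge:
        covered = covered[edge:-edge]
    return float(covered.mean())


def empirical_conservation(spec: MethodSpec, theta: float,
                           length: int = 50_000, n_reps: int = 100,
                           seed: int = 0,
                           edge_exclusion: Optional[int] = None) -> EmpiricalEstimate:
    """Monte-Carlo Cons(f,theta,k): per replicate, draw S, mutate to S',
    select from both, and measure the fraction of bases covered by a k-mer
    present in both selections at the same position with the same string.

    The conservation closed forms describe bases away from the string ends
    (interior bases see the full complement of covering k-mers and windows),
    so by default ``window_span + k`` bases at each end are excluded from
    the denominator; pass ``edge_exclusion=0`` for the raw whole-string
    fraction."""
    if length < 10 * spec.k:
        raise ValueError("sequence too short relative to k for a stable estimate")
    edge = spec.window_span + spec.k if edge_exclusion is None else edge_exclusion
    vals = []
    for r in range(n_reps):
        rng = _rng(seed, r)
        codes = random_codes(length, rng)
        mut, hit = mutate_codes(codes, theta, rng)
        vals.append(_conserved_fraction(codes, mut, hit, spec, edge))
    return EmpiricalEstimate.from_replicates(vals, seed)


def fraction_of_upper_bound(spec: MethodSpec, theta_grid: Sequence[float],
                            length: int = 50_000, n_reps: int = 100,
                            seed: int = 0, density=None):
    """Cons(f,theta,k) / (UB(d) . Pr(alpha(theta,k))) along a mutation-rate
    grid, as a pandas DataFrame.

    Closed-form conservation is used where available (1-local methods and
    the minimizer bound); otherwise the Monte-Carlo estimate.  ``density``
    defaults to the method's theoretical density and must be supplied for
    the miniception.
    """
    import pandas as pd

    if density is None:
        density = theory.theoretical_density(spec)
    try:
        pv = theory.probability_vector(spec)
        have_closed = True
    except ValueError:
        pv, have_closed = None, False
    closed_exact = have_closed and spec.locality == 1

    rows = []
    for i, theta in enumerate(theta_grid):
        ub = theory.conservation_upper_bound(density, theta, spec.k)
        closed = theory.conservation(pv, theta, method=spec).value if have_closed else float("nan")
        if closed_exact:
            mean = closed
            lo = hi = float("nan")
        else:
            est = empirical_conservation(spec, theta, length, n_reps,
                                         seed=seed * 1000 + i)
            mean, lo, hi = est.mean, est.ci_low, est.ci_high
        rows.append({"method": spec.describe(), "theta": float(theta),
                     "cons_mean": mean, "ci_low": lo, "ci_high": hi,
                     "closed_form": closed, "upper_bound": ub,
                     "fraction_of_ub": mean / ub if ub > 0 else float("nan")})
    return pd.DataFrame(rows)


def repetitiveness_stats(selection: SelectionResult) -> RepetitivenessStats:
    """Multiplicity profile of the selected k-mers (unique-match precision
    proxy: 1-local schemes re-select every copy of a repeated k-mer, so they
    are expected to yield fewer unique selections than a minimizer at equal
    density)."""
    if len(selection) == 0:
        warnings.warn("empty selection; zero repetitiveness stats", stacklevel=2)
        return RepetitivenessStats(0, 0, float("nan"))
    _, counts = np.unique(selection.kmer_codes(), return_counts=True)
    return RepetitivenessStats(
        n_selected=len(selection),
        n_unique=int((counts == 1).sum()),
        mean_multiplicity=float(counts.mean()),
    )


def max_gap(selection: SelectionResult) -> Optional[int]:
    """Largest distance between consecutive selected start positions,
    including the flanks to the first and last possible k-mer start; None
    for an empty selection (no guarantee observed)."""
    if len(selection) == 0:
        return None
    pos = selection.positions
    last = selection.seq_length - selection.k
    bounds = np.concatenate(([0], pos, [last]))
    return int(np.diff(bounds).max())
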