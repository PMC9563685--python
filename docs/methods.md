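# Methods

## Model and scope

All theory in this package is stated for strings with i.i.d. uniform
characters over Σ = {A,C,G,T} and a substitution-only mutation model:
each base of the mutated copy S′ differs from S independently with
probability θ, and a substituted base is uniform over the three other
letters.  No indels are modelled, and only the forward strand is analyzed
(a canonical-strand toggle exists on the selectors but is off by default
and outside the theory).  A selection method f maps a string to a set of
(k-mer, start) pairs; f is *q-local* when its output is the union of its
outputs over all (k+q−1)-length windows.  Syncmers and word rules are
1-local (the decision reads only the k-mer itself); minimizer-style rules
are w-local.

## The pseudo-random order

Wherever the theory assumes "a random permutation of k-mers", the
implementation realizes it as a seeded bijective 64-bit mixer (the
splitmix64 finalizer) applied to the 2-bit packing of the k-mer, which
bounds k at 32 (ample for the k ≤ 25 regimes studied here).  For fixed
length and seed the map is injective, hence a total order; equal k-mers
tie and every tie — at both the s-mer and k-mer level — is broken toward
the leftmost occurrence, matching the convention under which the closed
forms are derived.  Distinct seeds give effectively independent orders;
the test suite checks pairwise order balance across a seed sweep.  The
miniception uses two orders derived from one user seed: one for the
charged-k-mer test at length k0, one for ranking within a window; when a
window contains no charged k-mer the scheme falls back to the plain
window minimizer under the second order, which preserves the w-window
guarantee.

## Exact arithmetic

Permutation counts (factorials up to k−s+α, recurrences for open syncmers
and minimizers) are computed with Python's arbitrary-precision integers
and memoized; probabilities are `fractions.Fraction` values converted to
float only at interfaces.  The minimizer probability vector is computed by
two independent routes — the permutation-count recurrence and the
simplified closed form 1 − Pr(f,α) = (w−α+1)(w−α)/((w+1)w) — and any
disagreement beyond 10⁻¹² raises an internal-consistency error rather
than returning a value.  The run-length law is evaluated in whatever
numeric type θ arrives in (exact for `Fraction` inputs, float otherwise).

The closed forms assume all s-mers (resp. k-mers) within a window are
distinct; on random sequences the collision probability per window is
O((k−s+α)²/4ˢ), negligible for the s ≥ 10 regimes used in the shipped
comparisons but a visible approximation if s is pushed below ~7.  The
simulation engine is the quantitative check on this gap.

## Oracles before trust

Every closed form is certified against an independent brute-force
reference that shares no code with it: exhaustive permutation enumeration
(Sₙ for n ≤ 9) for the syncmer and minimizer counts, exhaustive
configuration sums (2^(2k−1), k ≤ 6) for the run-length law, and
exhaustive string enumeration (4^L, L ≤ 10) for the word method.  The
printed recurrences contain two typographic ambiguities — the
parenthesization of the run-length formula and whether the minimizer
recurrence's leading term carries the factor α — and both readings were
fixed by requiring exact agreement with the oracles over the full grid
(861 tuples) before acceptance.  The word-method inclusion–exclusion was
additionally validated at large α (up to k = 17) against an exact
transfer-matrix dynamic program, and the run-length law at k = 17 against
an exact longest-run DP, since the enumeration oracles cannot reach those
sizes.

## Simulation design

`random_string` draws codes from numpy's PCG64; one master seed is
spawned into per-replicate `SeedSequence((seed, rep))` streams so any
replicate is re-runnable in isolation.  Defaults mirror the comparison
protocol: 100 replicates of |S| = 50 000, with 95% normal-approximation
confidence intervals over replicate means.  Distinct experimental
conditions (method × θ cells in the acceptance suite) use distinct
canonical sub-seeds — each plotted point is its own independent
experiment.

Conservation bookkeeping is literal: a base is conserved when some k-mer
covering it is selected in both copies *at the same position with the
same string* (spurious cross-genome matches are excluded by
construction).  Because the closed forms describe bases away from the
string ends — interior bases see the full complement of covering k-mers
and windows — the estimators exclude `window_span + k` positions at each
end of the string by default (the raw whole-string fraction, which
carries an O(k/|S|) downward edge bias, is available via
`edge_exclusion=0` and is what the independent window-scan oracle
recomputes).  Density and empirical-probability-vector estimation use the
same interior restriction.

Non-ACGT characters never occur in generated sequences; on real FASTA
input any k-mer or window touching one is skipped and counted in the
result's `n_skipped_windows`.

## What the generator does and does not emulate

The generator produces exactly the regime the closed forms address: uniform
i.i.d. bases and independent substitutions.  Real genomes are not i.i.d.
(repeats, composition bias, low-complexity tracts), and real reads carry
indels.  Passing tests therefore certify the mathematics and the
implementation, not scheme performance on biological data; on real
sequences the conservation identity for 1-local schemes still holds
per-sequence (it is a consequence of locality, not of the base
distribution), but the closed-form *values* — which integrate over the
uniform ensemble — become approximations.

## Problem sizes and statistical choices

The shipped test suite uses the protocol sizes where the claim is about
the protocol itself (100 × 50 kb conservation cells; 100 × 100 kb
window-guarantee certificates; 20 × 1 Mb for the matched-density
repetitiveness comparison, paired on the same strings and assessed with a
one-sided t-test) and smaller sizes (tens of replicates, 2–50 kb) for
unit-level checks, keeping the whole suite under half a minute of
simulation time.  The repetitiveness effect at 1 Mb is small
(duplicated 15-mers are rare in 1 Mb of uniform sequence), which is why
that comparison is paired rather than two-sample.

One caveat is recorded openly: the acceptance-level equality check
performs 15 simultaneous 95%-CI containments; even under the exactly
correct theory the joint pass probability is only ≈ 0.95¹⁵ ≈ 0.46, so
individual ~2σ cell excursions are expected and are not evidence against
the identity.  The deeper certifications (exact DP cross-checks, a
2000-replicate bias bound of ≲ 3·10⁻⁴, CI calibration across 40
independent runs) are what establish correctness.

## Known limitations

- k ≤ 32 (64-bit packing); the theory computations themselves have no
  such bound but follow the same interface.
- Closed forms ignore within-window rank collisions (see above).
- The miniception's density has no closed form here; it is estimated
  empirically, and its k0/w tuning is left to the user rather than
  auto-searched.
- Word-set support is generic (any equal-length prefix set); only the
  (a,b,n) family ships with closed-form theory.
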