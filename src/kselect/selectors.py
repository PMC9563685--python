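"""Local k-mer selection schemes.

A k-mer selection method maps a string to a subset of its k-mers together
with their 0-based start positions.  All methods here are *q-local*: the
output on a string is the union of the outputs on its (k+q-1)-length
windows, so any two strings sharing such a window select the same k-mers
inside it.  The 1-local schemes (syncmers, word methods) decide per k-mer;
minimizer-style schemes are w-local.

Implemented schemes
-------------------
minimizer        smallest k-mer (seeded pseudo-random order) per window of
                 w consecutive k-mers; w-window guarantee.
closed_syncmer   k-mer selected iff the smallest of its k-s+1 constituent
                 s-mers sits in the first or last slot; (k-s)-window
                 guarantee.
open_syncmer     smallest s-mer sits in slot t (1-indexed); no window
                 guarantee in general.
abn_words        prefix is 'A' followed by n non-'A' letters.
word_set         prefix belongs to an explicit word set W.
miniception      window minimizer restricted to "charged" k-mers (those
                 that are closed syncmers at a shorter length k0), with a
                 plain-minimizer fallback for windows with no charged
                 k-mer.

Conventions: positions are 0-based half-open; ties in any ordering are
broken toward the leftmost occurrence; the forward strand only is
considered unless ``canonical=True``.  Windows containing non-ACGT
characters are skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._encoding import (
    INVALID_RANK,
    encode,
    decode,
    kmer_codes,
    kmer_ranks,
    kmer_rank,  # noqa: F401  (re-exported: the public rank primitive)
    mix64,
    seed_key,
)

METHODS = ("minimizer", "closed_syncmer", "open_syncmer", "abn_words",
           "word_set", "miniception")

_ONE_LOCAL = frozenset({"closed_syncmer", "open_syncmer", "abn_words", "word_set"})


@dataclass(frozen=True)
class MethodSpec:
    """A named selection method with its full parameterization.

    Parameters not used by ``method_name`` stay None.  ``order_seed`` keys
    the pseudo-random ordering (and, for the miniception, a second derived
    ordering for the charged-k-mer comparison).
    """

    method_name: str
    k: int
    w: Optional[int] = None
    s: Optional[int] = None
    t: Optional[int] = None
    n: Optional[int] = None
    words: Optional[frozenset] = None
    k0: Optional[int] = None
    order_seed: int = 0
    canonical: bool = False

    def __post_init__(self):
        if self.method_name not in METHODS:
            raise ValueError(f"unknown method {self.method_name!r}; choose from {METHODS}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        m = self.method_name
        if m in ("minimizer", "miniception"):
            if self.w is None or self.w < 1:
                raise ValueError(f"{m} requires window size w >= 1")
        if m in ("closed_syncmer", "open_syncmer"):
            if self.s is None or not (1 <= self.s < self.k):
                raise ValueError(f"{m} requires 1 <= s < k")
        if m == "open_syncmer":
            if self.t is None or not (1 <= self.t <= self.k - self.s + 1):
                raise ValueError("open_syncmer requires 1 <= t <= k-s+1")
        if m == "abn_words":
            if self.n is None or self.n < 0 or self.n + 1 > self.k:
                raise ValueError("abn_words requires 0 <= n and n+1 <= k")
        if m == "word_set":
            if self.words is None:
                raise ValueError("word_set requires a word set")
            lens = {len(x) for x in self.words}
            if len(lens) > 1:
                raise ValueError("all words must have equal length")
            if lens and max(lens) > self.k:
                raise ValueError("word length must be <= k")
        if m == "miniception":
            if self.k0 is None:
                object.__setattr__(self, "k0", max(1, self.k - self.w))
            if not (1 <= self.k0 < self.k):
                raise ValueError("miniception requires 1 <= k0 < k")

    @property
    def locality(self) -> int:
        """q such that the method is q-local (1 for per-k-mer rules, w else)."""
        return 1 if self.method_name in _ONE_LOCAL else self.w

    @property
    def window_span(self) -> int:
        """Minimum string length the method can act on: k + locality - 1."""
        return self.k + self.locality - 1

    def select(self, seq: str, seq_id: str = "seq") -> "SelectionResult":
        return select(seq, self, seq_id=seq_id)

    def with_seed(self, order_seed: int) -> "MethodSpec":
        return replace(self, order_seed=order_seed)

    def describe(self) -> str:
        parts = [self.method_name, f"k={self.k}"]
        for name in ("w", "s", "t", "n", "k0"):
            v = getattr(self, name)
            if v is not None:
                parts.append(f"{name}={v}")
        if self.words is not None:
            parts.append(f"|W|={len(self.words)}")
        return " ".join(parts)


@dataclass(frozen=True)
class SelectedKmer:
    position: int
    kmer: str


@dataclass
class SelectionResult:
    """Ordered selection of k-mers from one sequence.

    ``positions`` is a strictly increasing int64 array of 0-based starts;
    k-mer strings are materialized lazily from the source sequence.
    """

    method: MethodSpec
    seq_id: str
    seq_length: int
    positions: np.ndarray
    _seq: str = field(repr=False, default="")
    n_skipped_windows: int = 0

    @property
    def k(self) -> int:
        return self.method.k

    def __len__(self) -> int:
        return len(self.positions)

    def kmer_at(self, position: int) -> str:
        return self._seq[position : position + self.k]

    @property
    def kmers(self) -> list[str]:
        return [self.kmer_at(int(p)) for p in self.positions]

    @property
    def selected(self) -> list[SelectedKmer]:
        return [SelectedKmer(int(p), self.kmer_at(int(p))) for p in self.positions]

    def __iter__(self) -> Iterator[SelectedKmer]:
        return iter(self.selected)

    def kmer_codes(self) -> np.ndarray:
        """uint64 2-bit packing of every selected k-mer (for multiplicity
        counting without building strings)."""
        codes, valid = encode(self._seq)
        packed, _ = kmer_codes(codes, valid, self.k)
        return packed[self.positions]

    @property
    def density(self) -> float:
        """Fraction of the sequence's k-mers that were selected."""
        n_kmers = self.seq_length - self.k + 1
        return len(self.positions) / n_kmers if n_kmers > 0 else float("nan")


# ---------------------------------------------------------------------------
# core position-level routines (operate on coded arrays; shared with the
# simulation module, which bypasses string construction)
# ---------------------------------------------------------------------------

def _window_all_valid(kmer_valid: np.ndarray, w: int) -> np.ndarray:
    bad = (~kmer_valid).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    return (cs[w:] - cs[:-w]) == 0


def _minimizer_positions(ranks: np.ndarray, w: int) -> tuple[np.ndarray, int]:
    """Leftmost argmin per w-window of k-mer ranks; windows containing an
    invalid k-mer are skipped.  Returns (unique positions, skipped count)."""
    m = ranks.shape[0]
    if m < w:
        return np.empty(0, dtype=np.int64), 0
    win = sliding_window_view(ranks, w)
    ok = _window_all_valid(ranks != INVALID_RANK, w)
    idx = win.argmin(axis=1) + np.arange(m - w + 1)
    return np.unique(idx[ok]), int((~ok).sum())


def _syncmer_argmin(codes: np.ndarray, valid: np.ndarray, k: int, s: int,
                    seed: int, stream: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Per k-mer: leftmost position (0-indexed slot) of the minimal s-mer
    among its k-s+1 constituent s-mers.  Returns (slot, kmer_valid)."""
    sranks = kmer_ranks(codes, valid, s, seed, stream)
    wlen = k - s + 1
    m = sranks.shape[0]
    if m < wlen:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = sliding_window_view(sranks, wlen)
    ok = _window_all_valid(sranks != INVALID_RANK, wlen)
    return win.argmin(axis=1), ok


def _select_mask(codes: np.ndarray, valid: np.ndarray, spec: MethodSpec
                 ) -> tuple[np.ndarray, int]:
    """Boolean per-k-mer selection mask for 1-local methods, or per-position
    selected mask for window methods.  Returns (mask over n-k+1 positions,
    number of skipped windows/k-mers)."""
    k = spec.k
    n = codes.shape[0]
    m = n - k + 1
    name = spec.method_name

    if name == "minimizer":
        ranks = kmer_ranks(codes, valid, k, spec.order_seed)
        pos, skipped = _minimizer_positions(ranks, spec.w)
        mask = np.zeros(m, dtype=bool)
        mask[pos] = True
        return mask, skipped

    if name == "miniception":
        return _miniception_mask(codes, valid, spec)

    if name in ("closed_syncmer", "open_syncmer"):
        slot, ok = _syncmer_argmin(codes, valid, k, spec.s, spec.order_seed)
        if name == "closed_syncmer":
            sel = (slot == 0) | (slot == k - spec.s)
        else:
            sel = slot == spec.t - 1
        return sel & ok, int((~ok).sum())

    # prefix methods
    _, kvalid = kmer_codes(codes, valid, k)
    if name == "abn_words":
        ell = spec.n + 1
        sel = codes[:m] == 0
        for j in range(1, ell):
            sel &= codes[j : j + m] != 0
    else:  # word_set
        if not spec.words:
            return np.zeros(m, dtype=bool), int((~kvalid).sum())
        ell = len(next(iter(spec.words)))
        packed_pref, _ = kmer_codes(codes, valid, ell)
        word_codes = np.sort(np.array(
            [_pack_word(wd) for wd in spec.words], dtype=np.uint64))
        sel = np.isin(packed_pref[:m], word_codes)
    return sel & kvalid, int((~kvalid).sum())


def _pack_word(word: str) -> int:
    codes, valid = encode(word)
    if not valid.all():
        raise ValueError(f"non-ACGT character in word {word!r}")
    packed, _ = kmer_codes(codes, valid, len(word))
    return int(packed[0])


def _miniception_mask(codes: np.ndarray, valid: np.ndarray, spec: MethodSpec
                      ) -> tuple[np.ndarray, int]:
    k, w, k0 = spec.k, spec.w, spec.k0
    n = codes.shape[0]
    m = n - k + 1
    # charged: the k-mer is a closed syncmer at smer length k0
    slot, ok = _syncmer_argmin(codes, valid, k, k0, spec.order_seed, stream=1)
    charged = ((slot == 0) | (slot == k - k0)) & ok
    # rank among charged by a second order; uncharged k-mers are pushed above
    # every charged one so a window argmin falls back to the plain minimizer
    # (by the same order) only when nothing is charged.
    ranks = kmer_ranks(codes, valid, k, spec.order_seed, stream=2)
    eff = (ranks >> np.uint64(1)) | np.where(
        charged, np.uint64(0), np.uint64(1) << np.uint64(62))
    eff[~ok] = INVALID_RANK
    pos, skipped = _minimizer_positions(eff, w)
    mask = np.zeros(m, dtype=bool)
    mask[pos] = True
    return mask, skipped


def select_positions(codes: np.ndarray, valid: np.ndarray, spec: MethodSpec
                     ) -> np.ndarray:
    """Selected 0-based start positions for a coded sequence (fast path)."""
    mask, _ = _select_mask(codes, valid, spec)
    return np.flatnonzero(mask).astype(np.int64)


def select(seq: str, spec: MethodSpec, seq_id: str = "seq") -> SelectionResult:
    """Apply a selection method to a sequence string."""
    if len(seq) < spec.window_span:
        warnings.warn(
            f"sequence {seq_id!r} shorter than the method span "
            f"{spec.window_span}; empty selection", stacklevel=2)
        return SelectionResult(spec, seq_id, len(seq),
                               np.empty(0, dtype=np.int64), seq)
    codes, valid = encode(seq)
    mask, skipped = _select_mask(codes, valid, spec)
    if spec.canonical:
        rc_mask, _ = _select_mask(3 - codes[::-1], valid[::-1], spec)
        mask = mask | rc_mask[::-1]
    return SelectionResult(spec, seq_id, len(seq),
                           np.flatnonzero(mask).astype(np.int64), seq,
                           n_skipped_windows=skipped)


# ---------------------------------------------------------------------------
# convenience wrappers, one per scheme
# ---------------------------------------------------------------------------

def select_minimizers(seq: str, k: int, w: int, order_seed: int = 0,
                      seq_id: str = "seq") -> SelectionResult:
    return select(seq, MethodSpec("minimizer", k=k, w=w, order_seed=order_seed), seq_id)


def select_closed_syncmers(seq: str, k: int, s: int, order_seed: int = 0,
                           seq_id: str = "seq") -> SelectionResult:
    return select(seq, MethodSpec("closed_syncmer", k=k, s=s, order_seed=order_seed), seq_id)


def select_open_syncmers(seq: str, k: int, s: int, t: int, order_seed: int = 0,
                         seq_id: str = "seq") -> SelectionResult:
    return select(seq, MethodSpec("open_syncmer", k=k, s=s, t=t, order_seed=order_seed), seq_id)


def select_abn_words(seq: str, k: int, n: int, seq_id: str = "seq") -> SelectionResult:
    return select(seq, MethodSpec("abn_words", k=k, n=n), seq_id)


def select_word_set(seq: str, k: int, words, seq_id: str = "seq") -> SelectionResult:
    return select(seq, MethodSpec("word_set", k=k, words=frozenset(words)), seq_id)


def select_miniception(seq: str, k: int, w: int, k0: Optional[int] = None,
                       order_seed: int = 0, seq_id: str = "seq") -> SelectionResult:
    return select(seq, MethodSpec("miniception", k=k, w=w, k0=k0, order_seed=order_seed), seq_id)


def abn_word_set(n: int) -> frozenset:
    """The explicit word set of the (a,b,n)-words rule: 'A' followed by n
    letters drawn from {C,G,T}."""
    import itertools
    return frozenset("A" + "".join(tail)
                     for tail in itertools.product("CGT", repeat=n))
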