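"""Low-level 2-bit nucleotide encoding and the seeded pseudo-random k-mer order.

Every selection scheme in this package that needs "a random ordering on
k-mers" realizes it the same way: the k-mer is packed into a 64-bit integer
(2 bits per base, A=0, C=1, G=2, T=3) and passed through a seeded bijective
64-bit mixer (the splitmix64 finalizer).  For a fixed k-mer length and seed
the map is injective, so it induces a total order on k-mers; distinct seeds
give effectively independent orders.
"""

from __future__ import annotations

import numpy as np

_U64 = np.uint64

# splitmix64 finalizer constants
_M1 = _U64(0xBF58476D1CE4E5B9)
_M2 = _U64(0x94D049BB133111EB)
_GOLDEN = 0x9E3779B97F4A7C15

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# An s-mer/k-mer rank reserved for invalid (non-ACGT) windows: larger than
# every real rank so invalid entries never win an argmin, and detectable.
INVALID_RANK = np.iinfo(np.uint64).max


def encode(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Map a string to (codes, valid): int8 codes in 0..3 and a validity mask.

    Non-ACGT characters (e.g. N) get code 0 with ``valid`` False; callers are
    responsible for skipping k-mers that touch them.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    valid = codes >= 0
    return np.where(valid, codes, 0).astype(np.int8), valid


def decode(codes: np.ndarray) -> str:
    return _BASES[np.asarray(codes, dtype=np.intp)].tobytes().decode("ascii")


def seed_key(seed: int, stream: int = 0) -> np.uint64:
    """Derive a 64-bit mixing key from a small user seed (one key per stream)."""
    z = (int(seed) * 0x100000001B3 + (stream + 1) * _GOLDEN) % (1 << 64)
    return _mix_scalar(_U64(z))


def _mix_scalar(z: np.uint64) -> np.uint64:
    return mix64(np.asarray([z], dtype=_U64))[0]


def mix64(x: np.ndarray) -> np.ndarray:
    """Vectorized splitmix64 finalizer — a bijection on uint64."""
    z = x.astype(_U64, copy=True)
    z ^= z >> _U64(30)
    z *= _M1
    z ^= z >> _U64(27)
    z *= _M2
    z ^= z >> _U64(31)
    return z


def kmer_codes(codes: np.ndarray, valid: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack every length-k window into a uint64 (2 bits/base, leftmost base
    most significant).  Returns (packed, kmer_valid) of length n-k+1.

    Requires k <= 32.
    """
    if not 1 <= k <= 32:
        raise ValueError(f"k must be in 1..32 for 64-bit packing, got {k}")
    n = codes.shape[0]
    if n < k:
        return np.empty(0, dtype=_U64), np.empty(0, dtype=bool)
    m = n - k + 1
    packed = np.zeros(m, dtype=_U64)
    for j in range(k):
        packed <<= _U64(2)
        packed |= codes[j : j + m].astype(_U64)
    # a k-mer is valid iff all k bases are valid
    bad = (~valid).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    kmer_valid = (cs[k:] - cs[:-k]) == 0
    return packed, kmer_valid


def kmer_ranks(codes: np.ndarray, valid: np.ndarray, k: int, seed: int,
               stream: int = 0) -> np.ndarray:
    """Pseudo-random rank of every k-mer of the coded sequence; invalid
    windows get INVALID_RANK."""
    packed, kmer_valid = kmer_codes(codes, valid, k)
    ranks = mix64(packed + seed_key(seed, stream))
    # mixing can produce INVALID_RANK itself with prob 2^-64; ignore
    ranks[~kmer_valid] = INVALID_RANK
    return ranks


def kmer_rank(kmer: str, seed: int) -> int:
    """Rank of a single k-mer under the seeded order (deterministic, and
    injective over k-mers of one length).

    Raises ValueError on non-ACGT characters.
    """
    codes, valid = encode(kmer)
    if not valid.all():
        bad = kmer[int(np.flatnonzero(~valid)[0])]
        raise ValueError(f"non-ACGT character {bad!r} in k-mer")
    packed, _ = kmer_codes(codes, valid, len(kmer))
    return int(mix64(packed + seed_key(seed, 0))[0])
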