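"""Canonical k-mer and spaced-seed hashing on 2-bit packed sequences.

All sequence hashing in the package flows through this module: the
multi-index Bloom filter hashes spaced-seed derived k-mers, the polisher
hashes contiguous k-mers, and the scaffolder hashes k-mers for minimizer
sketches. Hashes are strand-canonical 64-bit values: a window and its
reverse complement always map to the same value.

Implementation: bases are packed 2 bits each (A=0, C=1, G=2, T=3); the
packed integer of the forward window and of its reverse complement are
computed with vectorised shift-adds, the smaller of the two is salted and
passed through a splitmix64 finalizer. Spaced seeds must be symmetric
(palindromic care masks) so that the reverse complement of a masked window
is the masked reverse-complement window, which is what makes canonical
hashing possible for spaced seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

U64 = np.uint64
_UMAX = np.uint64(0xFFFFFFFFFFFFFFFF)

# base -> 2-bit code; anything outside ACGTacgt (incl. N) maps to 255
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """2-bit codes of ``seq`` as uint8; non-ACGT positions are 255."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def splitmix64(x: np.ndarray) -> np.ndarray:
    """Avalanche finalizer (splitmix64); elementwise on uint64 arrays."""
    with np.errstate(over="ignore"):
        z = (x + U64(0x9E3779B97F4A7C15)).astype(U64)
        z = (z ^ (z >> U64(30))) * U64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> U64(27))) * U64(0x94D049BB133111EB)
        return z ^ (z >> U64(31))


def _valid_windows(codes: np.ndarray, span: int) -> np.ndarray:
    """Boolean mask over window starts: True where no N in the window."""
    n = len(codes) - span + 1
    if n <= 0:
        return np.zeros(0, dtype=bool)
    bad = (codes == 255).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    return (cs[span:] - cs[:-span]) == 0


def canonical_kmer_hashes(
    codes: np.ndarray, k: int, salt: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Strand-canonical hashes of all contiguous k-mers.

    Returns ``(hashes, valid)``, one entry per k-mer start position.
    Positions whose k-mer contains N are flagged invalid (hash value
    undefined there). Requires ``k <= 32``.
    """
    if k > 32:
        raise ValueError("k must be <= 32 for 2-bit packing into 64 bits")
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=U64), np.zeros(0, dtype=bool)
    valid = _valid_windows(codes, k)
    c = np.where(codes == 255, 0, codes).astype(U64)
    fwd = np.zeros(n, dtype=U64)
    rc = np.zeros(n, dtype=U64)
    with np.errstate(over="ignore"):
        for j in range(k):
            col = c[j : j + n]
            fwd += col << U64(2 * (k - 1 - j))
            rc += (U64(3) - col) << U64(2 * j)
        canon = np.minimum(fwd, rc)
        h = splitmix64(canon ^ U64(salt & 0xFFFFFFFFFFFFFFFF) ^ U64(k))
    return h, valid


# --- spaced seeds -----------------------------------------------------------

# Half-masks (15 positions, weight 9 each, care at the outer end); each full
# pattern is half + '0' + reversed(half): span 31, weight 18, symmetric.
_SEED_HALVES = (
    "111010110100110",
    "110110101010101",
    "101101011001011",
)

_SEED_SALTS = (
    0x2545F4914F6CDD1D,
    0x9E6C63D0A9B4E51F,
    0x5851F42D4C957F2D,
    0xDA942042E4DD58B5,
    0xB5297A4D3125717C,
)


@dataclass(frozen=True)
class SpacedSeedSet:
    """An ordered set of ``h`` symmetric spaced-seed patterns.

    Each pattern is a string over {0,1} (1 = care position); all patterns
    share the same span and weight, have care positions at both ends, and
    are palindromic so that strand-canonical hashing is well defined.
    """

    patterns: tuple[str, ...]
    care: tuple[np.ndarray, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError("need at least one seed pattern")
        span = len(self.patterns[0])
        weight = self.patterns[0].count("1")
        for pat in self.patterns:
            if set(pat) - {"0", "1"}:
                raise ValueError(f"pattern {pat!r} is not binary")
            if len(pat) != span:
                raise ValueError("all patterns must share one span")
            if pat.count("1") != weight:
                raise ValueError("all patterns must share one weight")
            if pat[0] != "1" or pat[-1] != "1":
                raise ValueError("patterns need care positions at both ends")
            if pat != pat[::-1]:
                raise ValueError(
                    "patterns must be symmetric for canonical hashing"
                )
        object.__setattr__(
            self,
            "care",
            tuple(
                np.flatnonzero(np.frombuffer(p.encode(), np.uint8) == ord("1"))
                for p in self.patterns
            ),
        )

    @property
    def h(self) -> int:
        return len(self.patterns)

    @property
    def span(self) -> int:
        return len(self.patterns[0])

    @property
    def weight(self) -> int:
        return self.patterns[0].count("1")


def default_seeds(h: int = 3) -> SpacedSeedSet:
    """The built-in symmetric seed set (span 31, weight 18)."""
    if not 1 <= h <= len(_SEED_HALVES):
        raise ValueError(f"h must be in [1, {len(_SEED_HALVES)}]")
    pats = tuple(half + "0" + half[::-1] for half in _SEED_HALVES[:h])
    return SpacedSeedSet(pats)


def spaced_seed_hashes(
    codes: np.ndarray, seeds: SpacedSeedSet
) -> tuple[np.ndarray, np.ndarray]:
    """Canonical spaced-seed hashes for every window of the sequence.

    Returns ``(hashes, valid)`` where ``hashes`` has shape ``(n, h)`` for
    ``n = len(codes) - span + 1`` window start positions, and ``valid`` is a
    boolean mask (windows containing N are invalid and must be skipped).
    """
    span = seeds.span
    n = len(codes) - span + 1
    if n <= 0:
        return np.zeros((0, seeds.h), dtype=U64), np.zeros(0, dtype=bool)
    valid = _valid_windows(codes, span)
    c = np.where(codes == 255, 0, codes).astype(U64)
    out = np.empty((n, seeds.h), dtype=U64)
    with np.errstate(over="ignore"):
        for i, care in enumerate(seeds.care):
            w = len(care)
            fwd = np.zeros(n, dtype=U64)
            rc = np.zeros(n, dtype=U64)
            # symmetric seed: reverse complement hits the same care columns
            for j, cpos in enumerate(care):
                col = c[cpos : cpos + n]
                fwd += col << U64(2 * (w - 1 - j))
                rc += (U64(3) - col) << U64(2 * j)
            canon = np.minimum(fwd, rc)
            out[:, i] = splitmix64(canon ^ U64(_SEED_SALTS[i]))
    return out, valid


def hash_window(window: str, seeds: SpacedSeedSet) -> np.ndarray:
    """The ``h`` canonical hash values of one window of length ``span``.

    Raises on wrong window length; returns an empty array when the window
    contains N (such windows produce no hashes).
    """
    if len(window) != seeds.span:
        raise ValueError(
            f"window length {len(window)} != seed span {seeds.span}"
        )
    hashes, valid = spaced_seed_hashes(encode(window), seeds)
    if not valid[0]:
        return np.zeros(0, dtype=U64)
    return hashes[0]
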