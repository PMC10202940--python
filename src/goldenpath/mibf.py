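"""Dynamic multi-index Bloom filter (miBf).

The miBf associates spaced-seed derived k-mers with small integer block IDs
(each ID standing for a genomic locus). It is built in two passes:

1. *Bloom pass*: every spaced-seed hash of every read that passes the
   length/quality filter sets a bit in a Bloom bit array. The bit array is
   then frozen and a rank (popcount) index is computed over it, which maps
   each set bit to a slot in an ID array sized to the number of set bits.
2. *Selection pass*: the ID array is filled incrementally as sequences are
   selected; IDs are queried and inserted in interleaved fashion. Unlike
   the static structure this design derives from, collision rescue is
   disabled: a colliding insertion simply overwrites the slot (newest
   wins), and the tile-tally threshold downstream absorbs the loss.

Because every filtered read contributed its bits in pass 1, the structure
has no false negatives: any window of a pass-1 read is "present" (all h
bits set) forever after.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

from .hashing import SpacedSeedSet, default_seeds, encode, spaced_seed_hashes
from .seqio import ReadRecord, mean_phred

U64 = np.uint64


def recommended_p(total_filtered_bases: int, min_p: int = 16) -> int:
    """log2 Bloom size giving <1% per-probe FPR at h=3 seeds.

    Allocates ~40 bits per filtered base (each base yields about one window,
    i.e. h=3 hash insertions), so the load factor stays near 3/40 and the
    per-probe false-positive rate below 1%.
    """
    if total_filtered_bases <= 0:
        raise ValueError("no usable reads: zero filtered bases")
    return max(min_p, math.ceil(math.log2(40 * total_filtered_bases)))


class MiBf:
    """Bloom bit array + rank array + ID array keyed by spaced-seed hashes.

    Lifecycle: construct, :meth:`insert_bits` for every pass-1 read, then
    :meth:`finalize`; afterwards :meth:`insert_block` / :meth:`query_windows`
    may be interleaved. :meth:`reset_ids` clears the ID array (used when a
    new silver path starts) without touching the shared bits.
    """

    def __init__(self, p: int, seeds: SpacedSeedSet | None = None) -> None:
        if not 6 <= p <= 40:
            raise ValueError("p (log2 bits) must be in [6, 40]")
        self.p = p
        self.seeds = seeds if seeds is not None else default_seeds()
        self._mask = U64((1 << p) - 1)
        self.words = np.zeros(1 << (p - 6), dtype=U64)
        self.frozen_bits = False
        self._rank_before: np.ndarray | None = None  # exclusive, per word
        self.ids: np.ndarray | None = None
        self.query_count = 0  # windows queried (for the linearity property)

    # --- pass 1: Bloom construction ----------------------------------------

    def insert_bits(self, hashes: np.ndarray) -> None:
        """Set the bits addressed by (flat) 64-bit hash values."""
        if self.frozen_bits:
            raise RuntimeError("bit array is frozen after pass 1")
        idx = hashes.ravel() & self._mask
        np.bitwise_or.at(self.words, (idx >> U64(6)).astype(np.int64),
                         U64(1) << (idx & U64(63)))

    def insert_sequence_bits(self, seq: str) -> int:
        """Hash every valid window of ``seq`` into the bit array.

        Returns the number of windows inserted.
        """
        hashes, valid = spaced_seed_hashes(encode(seq), self.seeds)
        if valid.any():
            self.insert_bits(hashes[valid])
        return int(valid.sum())

    def freeze(self) -> None:
        """Freeze the bit array; no further pass-1 insertions allowed."""
        self.frozen_bits = True

    def finalize(self) -> None:
        """Build the rank index and the (empty) ID array over frozen bits."""
        if not self.frozen_bits:
            raise RuntimeError("finalize requires a frozen bit array")
        if self._rank_before is not None:
            raise RuntimeError("finalize called twice")
        counts = np.bitwise_count(self.words).astype(np.int64)
        total = int(counts.sum())
        rank = np.zeros(len(self.words), dtype=np.int64)
        np.cumsum(counts[:-1], out=rank[1:])
        self._rank_before = rank
        self.ids = np.zeros(total, dtype=np.uint32)

    @property
    def popcount(self) -> int:
        if not self.frozen_bits:
            raise RuntimeError("not finalized")
        return len(self.ids)

    def rank(self, bit_pos: int) -> int:
        """Number of set bits strictly before ``bit_pos``."""
        return int(self._slots(np.array([bit_pos], dtype=U64))[0])

    def reset_ids(self) -> None:
        if self.ids is None:
            raise RuntimeError("not finalized")
        self.ids[:] = 0

    # --- bit/slot addressing ------------------------------------------------

    def _positions(self, hashes: np.ndarray) -> np.ndarray:
        return hashes & self._mask

    def _bits_set(self, pos: np.ndarray) -> np.ndarray:
        w = self.words[(pos >> U64(6)).astype(np.int64)]
        return ((w >> (pos & U64(63))) & U64(1)).astype(bool)

    def _slots(self, pos: np.ndarray) -> np.ndarray:
        """ID-array slot for each *set* bit position (rank of the bit)."""
        wi = (pos >> U64(6)).astype(np.int64)
        bi = pos & U64(63)
        below = self.words[wi] & ((U64(1) << bi) - U64(1))
        return self._rank_before[wi] + np.bitwise_count(below).astype(np.int64)

    # --- pass 2: interleaved insert / query ----------------------------------

    def insert_block(self, window_hashes: np.ndarray, block_id: int) -> None:
        """Write ``block_id`` into the slots of all given window hashes.

        ``window_hashes`` has shape (n_windows, h). Every probed bit must
        already be set (pass-1 contract); pre-existing nonzero slots are
        overwritten (collision rescue disabled).
        """
        if self.ids is None:
            raise RuntimeError("finalize() must run before insertions")
        if block_id <= 0:
            raise ValueError("block IDs are positive (0 = empty slot)")
        pos = self._positions(window_hashes.ravel())
        if not self._bits_set(pos).all():
            raise RuntimeError(
                "insert probed an unset bit; sequence was not in pass 1"
            )
        self.ids[self._slots(pos)] = block_id

    def query_windows(self, window_hashes: np.ndarray) -> np.ndarray:
        """IDs stored at the h slots of each window; 0 marks 'absent'.

        Returns an (n_windows, h) uint32 array. A window whose h bits are
        not all set returns a row of zeros (the window is absent from the
        filter). Increments the query counter by n_windows.
        """
        if self.ids is None:
            raise RuntimeError("finalize() must run before queries")
        n = window_hashes.shape[0]
        self.query_count += n
        out = np.zeros((n, window_hashes.shape[1]), dtype=np.uint32)
        if n == 0:
            return out
        pos = self._positions(window_hashes)
        present = self._bits_set(pos.ravel()).reshape(pos.shape).all(axis=1)
        if present.any():
            sel = pos[present]
            out[present] = self.ids[self._slots(sel.ravel())].reshape(sel.shape)
        return out

    def query_window(self, window_hashes: np.ndarray) -> list[int]:
        """Nonzero block IDs stored for one window (possibly empty)."""
        row = self.query_windows(window_hashes.reshape(1, -1))[0]
        return [int(v) for v in row if v != 0]

    @property
    def nbytes(self) -> int:
        n = self.words.nbytes
        if self._rank_before is not None:
            n += self._rank_before.nbytes
        if self.ids is not None:
            n += self.ids.nbytes
        return n


def build_bloom(
    reads: Iterable[ReadRecord],
    min_length: int,
    min_mean_phred: float,
    seeds: SpacedSeedSet | None = None,
    p: int | None = None,
) -> MiBf:
    """Pass-1 construction: Bloom bits from all filter-passing reads.

    A read passes iff it is at least ``min_length`` bp long and its mean
    Phred score is strictly greater than ``min_mean_phred``. When ``p`` is
    None the reads are buffered to size the filter first. Raises if no read
    passes ("no usable reads").
    """
    seeds = seeds if seeds is not None else default_seeds()

    def _passes(rec: ReadRecord) -> bool:
        if len(rec) < min_length:
            return False
        return rec.qual is None or mean_phred(rec.qual) > min_mean_phred

    if p is None:
        buffered = [r for r in reads if _passes(r)]
        total = sum(len(r) for r in buffered)
        if total == 0:
            raise ValueError("no usable reads passed the length/quality filter")
        mibf = MiBf(recommended_p(total), seeds)
        for rec in buffered:
            mibf.insert_sequence_bits(rec.seq)
    else:
        mibf = MiBf(p, seeds)
        total = 0
        for rec in reads:
            if _passes(rec):
                total += len(rec)
                mibf.insert_sequence_bits(rec.seq)
        if total == 0:
            raise ValueError("no usable reads passed the length/quality filter")
    mibf.freeze()
    return mibf
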