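"""Targeted k-mer polishing of goldtigs.

Each goldtig gets one small Bloom filter per k-mer size, populated only
with the canonical k-mers of the reads mapped to that goldtig. The draft is
then scanned: a position whose covering k-mer is absent from the filter is
a suspect error, and candidate edits (substitutions first, then short
insertions and deletions) are verified against the filter before being
applied. Longer k-mers give specificity, shorter ones sensitivity, so
detection runs at every k in ``k_list`` from largest to smallest with
per-locus fallback to the smaller sizes, and whole passes repeat until no
edit is accepted.

Verification: a candidate is scored by how many of the k-mers in its verify
window (k k-mers covering the edited base for substitutions, 2k-1 for
indels, the window clipped at sequence ends) are present in the filter. The
candidate with the highest score is accepted iff its score reaches
``max(min_support, score_of_the_unedited_window + 2)`` (capped by the
window size). A fully-present window is the strong special case of this
rule; the support-count form is what lets errors that sit within k bp of a
neighbouring error be corrected iteratively, outside-in, instead of being
permanently blocked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .hashing import U64, canonical_kmer_hashes, encode, splitmix64

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class PolishParams:
    k_list: tuple[int, ...] = (32, 28, 24, 20)
    bits_per_kmer: int = 14  # <1% FPR at 3 hash probes, even at 2^p boundary
    num_hashes: int = 3
    max_indel: int = 3
    min_support: int = 3
    min_count: int = 2  # k-mer multiplicity needed to enter a filter
    rounds: int = 6

    def __post_init__(self) -> None:
        if list(self.k_list) != sorted(set(self.k_list), reverse=True):
            raise ValueError("k_list must be strictly descending")
        if self.max_indel < 0 or self.min_support < 1 or self.rounds < 1:
            raise ValueError("invalid polishing parameters")


class KmerBloom:
    """Plain Bloom filter over canonical k-mer hashes (double hashing)."""

    def __init__(self, expected_kmers: int, bits_per_kmer: int = 14,
                 num_hashes: int = 3) -> None:
        p = max(10, int(np.ceil(np.log2(max(1, expected_kmers) * bits_per_kmer))))
        self.p = p
        self._mask = U64((1 << p) - 1)
        self.words = np.zeros(1 << (p - 6), dtype=U64)
        self.num_hashes = num_hashes
        self.n_inserted = 0

    def _probes(self, hashes: np.ndarray, i: int) -> np.ndarray:
        with np.errstate(over="ignore"):
            h2 = splitmix64(hashes ^ U64(0xA24BAED4963EE407)) | U64(1)
            return (hashes + U64(i) * h2) & self._mask

    def insert(self, hashes: np.ndarray) -> None:
        for i in range(self.num_hashes):
            pos = self._probes(hashes, i)
            np.bitwise_or.at(self.words, (pos >> U64(6)).astype(np.int64),
                             U64(1) << (pos & U64(63)))
        self.n_inserted += len(hashes)

    def contains(self, hashes: np.ndarray) -> np.ndarray:
        out = np.ones(len(hashes), dtype=bool)
        for i in range(self.num_hashes):
            pos = self._probes(hashes, i)
            w = self.words[(pos >> U64(6)).astype(np.int64)]
            out &= ((w >> (pos & U64(63))) & U64(1)).astype(bool)
        return out


@dataclass(frozen=True)
class EditRecord:
    """One accepted edit, in draft coordinates at the time of application."""

    goldtig: str
    pos: int
    type: str  # 'sub' | 'ins' | 'del'
    before: str
    after: str


def replay_edits(seq: str, edits: Iterable[EditRecord]) -> str:
    """Apply an edit log in order; reproduces the polished sequence."""
    for e in edits:
        if e.type == "sub":  # same-length replacement, 1+ bases
            assert seq[e.pos : e.pos + len(e.before)] == e.before
            seq = seq[: e.pos] + e.after + seq[e.pos + len(e.before) :]
        elif e.type == "ins":
            seq = seq[: e.pos] + e.after + seq[e.pos :]
        elif e.type == "del":
            assert seq[e.pos : e.pos + len(e.before)] == e.before
            seq = seq[: e.pos] + seq[e.pos + len(e.before) :]
        else:
            raise ValueError(f"unknown edit type {e.type!r}")
    return seq


def build_targeted_filters(
    mapped_reads: Sequence[str], params: PolishParams
) -> dict[int, KmerBloom]:
    """One Bloom filter per k over the canonical k-mers of the mapped reads.

    Only k-mers observed at least ``min_count`` times across the mapped
    reads enter a filter: erroneous k-mers are overwhelmingly singletons at
    typical long-read error rates, while genomic k-mers recur across the
    pile-up, so the multiplicity cutoff is what gives the filters their
    discriminative power. K-mers containing N are skipped. Filters are
    sized for roughly <1% false-positive rate at the observed k-mer volume.
    """
    filters: dict[int, KmerBloom] = {}
    for k in params.k_list:
        chunks = []
        for read in mapped_reads:
            h, valid = canonical_kmer_hashes(encode(read), k)
            if valid.any():
                chunks.append(h[valid])
        if chunks:
            allh = np.sort(np.concatenate(chunks))
            if params.min_count > 1:
                uniq, counts = np.unique(allh, return_counts=True)
                keep = uniq[counts >= params.min_count]
            else:
                keep = np.unique(allh)
        else:
            keep = np.zeros(0, dtype=np.uint64)
        bf = KmerBloom(max(1, len(keep)), params.bits_per_kmer,
                       params.num_hashes)
        if len(keep):
            bf.insert(keep)
        filters[k] = bf
    return filters


def _presence(seq: str, k: int, bf: KmerBloom) -> np.ndarray:
    """Presence of each draft k-mer; N-containing k-mers count as present
    (they are never edit targets)."""
    h, valid = canonical_kmer_hashes(encode(seq), k)
    pres = bf.contains(h)
    pres[~valid] = True
    return pres


def _patch_presence(
    new_seq: str, pres_old: np.ndarray, j: int, delta: int, k: int,
    bf: KmerBloom,
) -> np.ndarray:
    """Presence array after an edit at ``j`` with length change ``delta``.

    Only k-mers overlapping the edited locus change; the head is kept, the
    tail is shifted, and the window around the edit is re-hashed.
    """
    n_new = len(new_seq) - k + 1
    if n_new <= 0:
        return np.zeros(0, dtype=bool)
    lo = max(0, j - k + 1)
    tail_new = j + k + abs(delta)
    tail_old = tail_new - delta
    if tail_new >= n_new or tail_old >= len(pres_old) or tail_old < 0:
        mid = _presence(new_seq[lo:], k, bf)
        return np.concatenate([pres_old[:lo], mid])
    mid = _presence(new_seq[lo : tail_new + k - 1], k, bf)
    return np.concatenate([pres_old[:lo], mid, pres_old[tail_old:]])


def _batch_scores(
    regions: Sequence[str],
    k: int,
    bf: KmerBloom,
    witness_idx: Sequence[int] | None = None,
) -> list[tuple[int, bool]]:
    """Present-k-mer count of each region plus one witness k-mer's presence.

    Regions are joined with an N separator, so k-mers never span two
    regions (N-containing k-mers are invalid). Each region is a candidate
    verify window whose first k-mer ends at the edited base;
    ``witness_idx[i]`` selects which k-mer of region ``i`` must vouch for
    the edit (0 = the first). For insertions the witness is the k-mer that
    ends one base past the inserted run: it spans the whole insert plus the
    junction back into the original sequence, so an insert cannot certify
    itself merely by extending the clean left context.
    """
    joined = "N".join(regions)
    if len(joined) < k:
        return [(0, False)] * len(regions)
    h, valid = canonical_kmer_hashes(encode(joined), k)
    ok = bf.contains(h) & valid
    good = np.zeros(len(h) + 1, dtype=np.int64)
    np.cumsum(ok, out=good[1:])
    scores = []
    off = 0
    for i, r in enumerate(regions):
        lo = off
        hi = max(lo, off + len(r) - k + 1)
        hi = min(hi, len(h))
        lo = min(lo, len(h))
        wi = lo + (witness_idx[i] if witness_idx is not None else 0)
        witness = bool(ok[wi]) if lo <= wi < hi else False
        scores.append((int(good[hi] - good[lo]), witness))
        off += len(r) + 1
    return scores


def _candidates(seq: str, j: int, indel_len: int):
    """Deterministic candidate edits at locus j, one indel-length tier.

    Tier 1 holds the substitutions and single-base indels; higher tiers add
    only the longer insertions/deletions of exactly that length. Tiers are
    searched in order and the search stops at the first accepting tier, so
    the cheap single-base repairs (the vast majority) stay cheap.
    """
    if indel_len == 1:
        cur = seq[j]
        for b in _BASES:
            if b != cur:
                yield ("sub", b, 0)
    else:
        # multi-base substitution over seq[j:j+d]: repairs tight error
        # pairs whose members sit closer than the evidence a single edit
        # could ever gather (every covering k-mer spans both errors)
        if j + indel_len <= len(seq):
            for combo in product(_BASES, repeat=indel_len):
                cand = "".join(combo)
                if cand[0] != seq[j] and cand != seq[j : j + indel_len]:
                    yield ("msub", cand, indel_len)
    for combo in product(_BASES, repeat=indel_len):
        yield ("ins", "".join(combo), 0)
    yield ("del", "", indel_len)


def _try_fix(
    seq: str, j: int, k: int, bf: KmerBloom, params: PolishParams
) -> tuple[str, EditRecord] | None:
    """Attempt one edit at locus ``j`` verified at k-mer size ``k``.

    All candidates at this k are scored in one batch; the best-scoring
    candidate wins (ties resolved by the fixed candidate order), provided
    it clears ``max(min_support, unedited score + 2)``.
    """
    for tier in range(1, params.max_indel + 1):
        result = _try_fix_tier(seq, j, k, bf, params, tier)
        if result is not None:
            return result
    return None


def _try_fix_tier(
    seq: str, j: int, k: int, bf: KmerBloom, params: PolishParams, tier: int
) -> tuple[str, EditRecord] | None:
    L = len(seq)
    ws = max(0, j - k + 1)

    cands = [c for c in _candidates(seq, j, tier) if j + c[2] <= L]
    regions: list[str] = []
    meta: list[tuple[str, str, int, int, int]] = []  # type, repl, dlen, avail, n_win
    widx: list[int] = []
    for etype, repl, dlen in cands:
        if etype == "sub":
            n_win, delta = k, 0
            local = seq[ws:j] + repl + seq[j + 1 : ws + n_win + k - 1]
            wit = 0
        elif etype == "msub":
            n_win, delta = k + dlen - 1, 0
            local = seq[ws:j] + repl + seq[j + dlen : ws + n_win + k - 1]
            wit = dlen - 1  # the k-mer ending at the last replaced base
        elif etype == "ins":
            n_win, delta = 2 * k - 1, len(repl)
            local = seq[ws:j] + repl + seq[j : ws + n_win + k - 1]
            wit = delta  # spans the whole insert plus the junction base
        else:
            n_win, delta = 2 * k - 1, -dlen
            local = seq[ws:j] + seq[j + dlen : ws + n_win + k - 1 + dlen]
            wit = 0
        avail = max(0, min(n_win, (L + delta) - k + 1 - ws))
        local = local[: avail + k - 1]
        regions.append(local)
        meta.append((etype, repl, dlen, avail, n_win))
        widx.append(wit)
    # unedited windows, for the no-edit baselines (sub and indel widths)
    regions.append(seq[ws : ws + (2 * k - 1) + k - 1])
    widx.append(0)
    batch = _batch_scores(regions, k, bf, widx)
    base_indel = batch[-1][0]
    base_sub = _batch_scores([seq[ws : ws + k + k - 1]], k, bf)[0][0]

    best: tuple[int, int] | None = None  # (score, candidate index)
    for idx, ((etype, repl, dlen, avail, n_win), (score, witness)) in enumerate(
        zip(meta, batch[:-1])
    ):
        if avail == 0 or not witness:
            continue  # the witness k-mer spanning the edit must be present
        base = base_sub if etype in ("sub", "msub") else base_indel
        threshold = min(avail, max(params.min_support, base + 2))
        if score >= threshold and (best is None or score > best[0]):
            best = (score, idx)

    if best is None:
        return None
    etype, repl, dlen, _, _ = meta[best[1]]
    if etype == "sub":
        edit = EditRecord("", j, "sub", seq[j], repl)
        new_seq = seq[:j] + repl + seq[j + 1 :]
    elif etype == "msub":
        edit = EditRecord("", j, "sub", seq[j : j + dlen], repl)
        new_seq = seq[:j] + repl + seq[j + dlen :]
    elif etype == "ins":
        edit = EditRecord("", j, "ins", "", repl)
        new_seq = seq[:j] + repl + seq[j:]
    else:
        edit = EditRecord("", j, "del", seq[j : j + dlen], "")
        new_seq = seq[:j] + seq[j + dlen :]
    return new_seq, edit


def polish_goldtig(
    seq: str,
    filters: dict[int, KmerBloom],
    params: PolishParams,
    name: str = "",
) -> tuple[str, list[EditRecord]]:
    """Scan-and-fix polishing of one goldtig.

    Runs repeated rounds over ``k_list`` (largest k first). Within a pass at
    detection size k, each present-to-absent transition of the draft k-mer
    presence profile marks a suspect locus ``j = i + k - 1``; candidate
    edits are tried at k and then at each smaller size until one verifies.
    Unresolvable loci are left unchanged; the cursor strictly advances, so
    termination is guaranteed.
    """
    edits: list[EditRecord] = []
    k_list = [k for k in params.k_list if k in filters]
    if not k_list:
        return seq, edits
    k_small = k_list[-1]
    for _ in range(params.rounds):
        round_edits = 0
        for ki, k in enumerate(k_list):
            if len(seq) < k:
                continue
            bf = filters[k]
            pres = _presence(seq, k, bf)
            # corroboration track: a locus flagged at a large k is only
            # attempted if the small-k k-mer ending there is absent too;
            # coverage holes of the sparser large-k filter are skipped.
            pres_small = (
                pres if k == k_small
                else _presence(seq, k_small, filters[k_small])
            )
            i = 0
            max_pass_edits = len(pres) + 100  # safety: cursor must win
            while i < len(pres):
                if pres[i] or (i > 0 and not pres[i - 1]):
                    i += 1
                    continue
                j = i + k - 1  # first base newly covered by the absent k-mer
                si = j - k_small + 1
                if k != k_small and 0 <= si < len(pres_small) and pres_small[si]:
                    i += 1
                    continue
                fixed = None
                for kk in k_list[ki:]:
                    if len(seq) >= kk:
                        fixed = _try_fix(seq, j, kk, filters[kk], params)
                        if fixed is not None:
                            break
                if fixed is None:
                    i += 1
                    continue
                seq, edit = fixed
                delta = len(edit.after) - len(edit.before)
                edits.append(
                    EditRecord(name, edit.pos, edit.type, edit.before, edit.after)
                )
                round_edits += 1
                pres = _patch_presence(seq, pres, edit.pos, delta, k, bf)
                if k != k_small:
                    pres_small = _patch_presence(
                        seq, pres_small, edit.pos, delta, k_small,
                        filters[k_small],
                    )
                max_pass_edits -= 1
                if max_pass_edits <= 0:
                    break
                i += 1
        if round_edits == 0:
            break
    return seq, edits


def polish_all(
    goldtigs: dict[str, str],
    mapped_reads: dict[str, Sequence[str]],
    params: PolishParams,
) -> tuple[dict[str, str], list[EditRecord]]:
    """Polish every goldtig independently (deterministic in any order).

    A goldtig with no mapped reads passes through unpolished.
    """
    polished: dict[str, str] = {}
    log: list[EditRecord] = []
    for name in goldtigs:
        reads = mapped_reads.get(name, ())
        if not reads:
            logger.warning("goldtig %s has no mapped reads; left unpolished", name)
            polished[name] = goldtigs[name]
            continue
        filters = build_targeted_filters(reads, params)
        new_seq, edits = polish_goldtig(goldtigs[name], filters, params, name)
        polished[name] = new_seq
        log.extend(edits)
    return polished, log


def write_edit_log(edits: Iterable[EditRecord], path) -> None:
    with open(path, "w") as out:
        out.write("goldtig\tpos\ttype\tbefore\tafter\n")
        for e in edits:
            out.write(f"{e.goldtig}\t{e.pos}\t{e.type}\t{e.before}\t{e.after}\n")
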