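"""Golden-path read selection.

Reads are streamed twice. Pass 1 inserts the spaced-seed hashes of every
filter-passing read into the miBf bit array. Pass 2 streams the reads again
and, for each, splits it into tiles of ``t`` bp, queries each tile's windows
against the miBf and tallies the returned block IDs, refines the per-tile
assignments using neighbouring tiles, and then decides to *skip* the read
(all tiles assigned: no new genome content), *insert* it whole (no tile
assigned), or *trim and insert* (keep the longest run of unassigned tiles
plus one assigned flanking tile on each existing side). Inserted sequence is
split into blocks of ``b`` tiles, each block receiving the next consecutive
block ID, and its window hashes are written into the miBf ID array.

A silver path closes when it accumulates ``G * r`` bases; the ID array is
reset and the stream continues until ``M`` silver paths exist or the reads
run out. The concatenated silver paths are then run through the same loop
once more (no length/quality re-filtering) to produce the golden path, whose
sequences are the goldtigs of the draft assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from .hashing import SpacedSeedSet, default_seeds, encode, spaced_seed_hashes
from .mibf import MiBf, build_bloom
from .seqio import ReadRecord, mean_phred

logger = logging.getLogger(__name__)


@dataclass
class GoldPathParams:
    """Tunables of the selection stage (defaults follow the method)."""

    G: int  # estimated genome size, bp
    t: int = 1000  # tile length
    b: int = 10  # tiles per block
    x: int = 10  # tile-assignment tally threshold (strict >)
    m: int = 20_000  # minimum read length
    P: float = 15.0  # minimum mean Phred (strict >)
    r: float = 0.9  # per-silver-path coverage target
    M: int = 5  # number of silver paths
    seeds: SpacedSeedSet = field(default_factory=default_seeds)
    p: int | None = None  # log2 Bloom bits; None = auto-sized

    def __post_init__(self) -> None:
        if self.G <= 0:
            raise ValueError("genome size G must be positive")
        if self.t < self.seeds.span:
            raise ValueError("tile length must be at least the seed span")
        if self.b < 1 or self.M < 1 or self.r <= 0:
            raise ValueError("b >= 1, M >= 1 and r > 0 required")


def passes_filters(read: ReadRecord, params: GoldPathParams) -> bool:
    """Length at least ``m`` and mean Phred strictly above ``P``."""
    if len(read) < params.m:
        return False
    if read.qual is None:
        return True
    return mean_phred(read.qual) > params.P


def tile_and_block(
    length: int, params: GoldPathParams
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Tile a read of ``length`` bp and bin tiles into blocks.

    Returns ``(tiles, blocks)``: tiles as [start, end) bp ranges
    (``floor(L/t)`` of them, trailing bases appended to the last tile) and
    blocks as [first_tile, last_tile) index ranges of ``b`` tiles each, the
    final block possibly partial.
    """
    t, b = params.t, params.b
    if length < t:
        raise ValueError(f"read length {length} is shorter than one tile ({t})")
    n_tiles = length // t
    tiles = [(i * t, (i + 1) * t) for i in range(n_tiles)]
    tiles[-1] = (tiles[-1][0], length)  # trailing <t bp joins the last tile
    blocks = [(i, min(i + b, n_tiles)) for i in range(0, n_tiles, b)]
    return tiles, blocks


@dataclass
class TileTable:
    """Per-tile ID tallies and assignments for one read."""

    tiles: list[tuple[int, int]]
    counts: list[dict[int, int]]  # block ID -> tally, per tile
    best_id: list[int]  # preliminary best (0 = none)
    best_count: list[int]
    assigned: list[bool]
    final_id: list[int]

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)


@dataclass(frozen=True)
class ReadDecision:
    """Outcome for one read: skip, insert, or trim_insert with a tile range."""

    kind: str  # 'skip' | 'insert' | 'trim_insert'
    tile_range: tuple[int, int] | None = None  # [i, j) tiles kept


@dataclass
class PathRecord:
    """One emitted silver/golden sequence with read-of-origin provenance."""

    name: str
    seq: str
    source_read: str
    source_start: int  # coordinates in the original read, 0-based half-open
    source_end: int


class PathBuilder:
    """Accumulator for one silver or golden path."""

    def __init__(self, name_prefix: str, target_bases: float) -> None:
        self.name_prefix = name_prefix
        self.target_bases = target_bases
        self.records: list[PathRecord] = []
        self.base_total = 0
        self.next_block_id = 1

    @property
    def complete(self) -> bool:
        return self.base_total >= self.target_bases

    def append(self, seq: str, source: str, start: int, end: int) -> None:
        rec = PathRecord(
            name=f"{self.name_prefix}_{len(self.records)}",
            seq=seq,
            source_read=source,
            source_start=start,
            source_end=end,
        )
        self.records.append(rec)
        self.base_total += len(seq)


def _window_tiles(
    n_windows: int, span: int, tiles: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Tile index of each window start; -1 for windows crossing a boundary."""
    t = tiles[0][1] - tiles[0][0]
    starts = np.arange(n_windows)
    idx = np.minimum(starts // t, len(tiles) - 1)
    ends = np.array([e for _, e in tiles])
    crossing = starts + span > ends[idx]
    return np.where(crossing, -1, idx)


def tally_tiles(
    mibf: MiBf,
    seq: str,
    tiles: Sequence[tuple[int, int]],
    params: GoldPathParams,
) -> TileTable:
    """Query every within-tile window of ``seq`` and tally ID hits per tile.

    Each nonzero ID returned in one of the h slots of a window adds one to
    that tile's tally for the ID. Preliminary assignment: the argmax ID
    (ties to the smaller ID), assigned iff its count strictly exceeds ``x``.
    """
    hashes, valid = spaced_seed_hashes(encode(seq), params.seeds)
    tidx = _window_tiles(len(valid), params.seeds.span, tiles)
    use = valid & (tidx >= 0)
    ids = mibf.query_windows(hashes[use])
    wtile = tidx[use]

    counts: list[dict[int, int]] = [dict() for _ in tiles]
    if ids.size:
        flat_tile = np.repeat(wtile, ids.shape[1])
        flat_id = ids.ravel()
        nz = flat_id != 0
        if nz.any():
            key = flat_tile[nz].astype(np.int64) * (2**32) + flat_id[nz]
            uniq, cnt = np.unique(key, return_counts=True)
            for k, c in zip(uniq.tolist(), cnt.tolist()):
                counts[k >> 32][k & 0xFFFFFFFF] = c

    best_id, best_count, assigned = [], [], []
    for table in counts:
        if table:
            # max count, ties broken toward the smaller ID
            bid, bcnt = min(table.items(), key=lambda kv: (-kv[1], kv[0]))
        else:
            bid, bcnt = 0, 0
        best_id.append(bid)
        best_count.append(bcnt)
        assigned.append(bcnt > params.x)
    return TileTable(
        tiles=list(tiles),
        counts=counts,
        best_id=best_id,
        best_count=best_count,
        assigned=assigned,
        final_id=[bid if a else 0 for bid, a in zip(best_id, assigned)],
    )


def refine_assignments(table: TileTable, params: GoldPathParams) -> TileTable:
    """Neighbour-based refinement of preliminary tile assignments.

    Consecutive blocks of one inserted sequence carry consecutive IDs, so
    agreement within +/-1 of a neighbouring tile's ID is the natural
    locus-continuity signal. Two rules, applied in one left-to-right sweep
    followed by one right-to-left sweep:

    * promotion — an unassigned tile with an assigned neighbour of ID ``v``
      becomes assigned to ``v*`` if its own tally table holds some
      ``v* in {v-1, v, v+1}`` with count >= ceil(x/2) (best such candidate;
      ties to the smaller ID);
    * demotion — an assigned tile whose ID is more than 1 away from every
      assigned neighbour's ID and whose count < 2x is demoted.
    """
    x = params.x
    half = -(-x // 2)  # ceil(x/2)
    assigned = list(table.assigned)
    final_id = [bid if a else 0 for bid, a in zip(table.best_id, assigned)]
    n = table.n_tiles

    def sweep(order: range) -> None:
        for i in order:
            nbr_ids = [
                final_id[j]
                for j in (i - 1, i + 1)
                if 0 <= j < n and assigned[j]
            ]
            if not assigned[i]:
                cands: dict[int, int] = {}
                for v in nbr_ids:
                    for v_star in (v - 1, v, v + 1):
                        c = table.counts[i].get(v_star, 0)
                        if c >= half:
                            cands[v_star] = c
                if cands:
                    v_star, _ = min(cands.items(), key=lambda kv: (-kv[1], kv[0]))
                    assigned[i] = True
                    final_id[i] = v_star
            else:
                if nbr_ids and all(abs(final_id[i] - v) > 1 for v in nbr_ids):
                    if table.counts[i].get(final_id[i], 0) < 2 * x:
                        assigned[i] = False
                        final_id[i] = 0

    sweep(range(n))
    sweep(range(n - 1, -1, -1))
    return TileTable(
        tiles=table.tiles,
        counts=table.counts,
        best_id=table.best_id,
        best_count=table.best_count,
        assigned=assigned,
        final_id=final_id,
    )


def classify_read(table: TileTable) -> ReadDecision:
    """Skip / insert / trim-and-insert from the final tile assignments.

    Trim keeps the longest maximal run of unassigned tiles (ties to the
    leftmost run) extended by one assigned tile on each side that exists.
    """
    assigned = table.assigned
    if all(assigned):
        return ReadDecision("skip")
    if not any(assigned):
        return ReadDecision("insert", (0, table.n_tiles))

    best_run: tuple[int, int] | None = None
    i = 0
    n = table.n_tiles
    while i < n:
        if not assigned[i]:
            j = i
            while j < n and not assigned[j]:
                j += 1
            if best_run is None or (j - i) > (best_run[1] - best_run[0]):
                best_run = (i, j)
            i = j
        else:
            i += 1
    lo, hi = best_run
    if lo > 0:
        lo -= 1  # one assigned flanking tile, when it exists
    if hi < n:
        hi += 1
    return ReadDecision("trim_insert", (lo, hi))


def insert_decision(
    mibf: MiBf,
    read: ReadRecord | PathRecord,
    decision: ReadDecision,
    builder: PathBuilder,
    params: GoldPathParams,
) -> None:
    """Insert the retained subsequence into the miBf and the path.

    The retained range is re-tiled and re-blocked; each block consumes the
    builder's next consecutive block ID and has all its window hashes
    ID-inserted. The subsequence is appended to the path with provenance in
    original-read coordinates.
    """
    if decision.kind == "skip":
        raise ValueError("skip decisions are not inserted")
    tiles, _ = tile_and_block_or_single(len(read.seq), params)
    lo, hi = decision.tile_range
    bp_lo, bp_hi = tiles[lo][0], tiles[hi - 1][1]
    sub = read.seq[bp_lo:bp_hi]

    sub_tiles, sub_blocks = tile_and_block_or_single(len(sub), params)
    hashes, valid = spaced_seed_hashes(encode(sub), params.seeds)
    starts = np.arange(len(valid))
    for b_lo, b_hi in sub_blocks:
        blk_start, blk_end = sub_tiles[b_lo][0], sub_tiles[b_hi - 1][1]
        inside = valid & (starts >= blk_start) & (
            starts + params.seeds.span <= blk_end
        )
        if inside.any():
            mibf.insert_block(hashes[inside], builder.next_block_id)
        builder.next_block_id += 1

    if isinstance(read, PathRecord):
        src = read.source_read
        src_lo = read.source_start + bp_lo
        src_hi = read.source_start + bp_hi
    else:
        src, src_lo, src_hi = read.name, bp_lo, bp_hi
    builder.append(sub, src, src_lo, src_hi)


def tile_and_block_or_single(
    length: int, params: GoldPathParams
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Like :func:`tile_and_block` but sub-tile sequences form one tile.

    Sequences shorter than one tile arise in the golden round (trimmed
    silver sequences are not re-filtered by length); they are treated as a
    single tile so every base can still be evaluated and emitted.
    """
    if length >= params.t:
        return tile_and_block(length, params)
    return [(0, length)], [(0, 1)]


@dataclass
class SelectionResult:
    silver_paths: list[list[PathRecord]]
    goldtigs: list[PathRecord]
    stats: dict


def _selection_loop(
    mibf: MiBf,
    records: Iterator[ReadRecord | PathRecord],
    params: GoldPathParams,
    name_prefix: str,
    target_bases: float,
    max_paths: int,
    apply_filters: bool,
    stats: dict,
) -> list[list[PathRecord]]:
    """Stream records once, building up to ``max_paths`` paths."""
    paths: list[list[PathRecord]] = []
    builder = PathBuilder(f"{name_prefix}{len(paths)}", target_bases)
    for rec in records:
        if apply_filters:
            if isinstance(rec, ReadRecord) and not passes_filters(rec, params):
                continue
        if len(rec.seq) < params.seeds.span:
            continue  # too short to hash; contributes nothing
        stats["bases_processed"] += len(rec.seq)
        tiles, _ = tile_and_block_or_single(len(rec.seq), params)
        table = tally_tiles(mibf, rec.seq, tiles, params)
        table = refine_assignments(table, params)
        decision = classify_read(table)
        stats[f"n_{decision.kind}"] += 1
        if decision.kind == "skip":
            continue
        insert_decision(mibf, rec, decision, builder, params)
        if builder.complete:
            paths.append(builder.records)
            if len(paths) >= max_paths:
                return paths
            mibf.reset_ids()
            builder = PathBuilder(f"{name_prefix}{len(paths)}", target_bases)
    if builder.records:
        paths.append(builder.records)
    return paths


def build_paths(
    reads: Callable[[], Iterable[ReadRecord]] | Sequence[ReadRecord],
    params: GoldPathParams,
) -> SelectionResult:
    """Full selection: pass-1 Bloom, silver paths, then the golden path.

    ``reads`` is either a sequence or a zero-argument callable returning a
    fresh iterator (so files can be streamed twice without buffering).
    """
    stream = reads if callable(reads) else (lambda: iter(reads))

    mibf = build_bloom(stream(), params.m, params.P, params.seeds, params.p)
    mibf.finalize()
    stats = {
        "bases_processed": 0,
        "n_skip": 0,
        "n_insert": 0,
        "n_trim_insert": 0,
        "bloom_p": mibf.p,
        "mibf_bytes": mibf.nbytes,
    }

    silver = _selection_loop(
        mibf,
        iter(stream()),
        params,
        name_prefix="silver",
        target_bases=params.G * params.r,
        max_paths=params.M,
        apply_filters=True,
        stats=stats,
    )
    silver_bases = sum(len(r.seq) for path in silver for r in path)
    if silver_bases < 0.5 * params.G:
        logger.warning(
            "insufficient coverage: silver paths hold %d bases < 0.5 x G (%d)",
            silver_bases,
            params.G,
        )

    # golden round: the concatenated silver sequences re-enter the same loop,
    # sharing the pass-1 bit array (silver sequences are verbatim substrings
    # of pass-1 reads, so no false negatives are possible); only the ID
    # array is reset. Silver sequences bypass the m/P filter.
    mibf.reset_ids()
    silvertigs = [rec for path in silver for rec in path]
    golden = _selection_loop(
        mibf,
        iter(silvertigs),
        params,
        name_prefix="goldtig",
        target_bases=float("inf"),
        max_paths=1,
        apply_filters=False,
        stats=stats,
    )
    goldtigs = golden[0] if golden else []
    for i, rec in enumerate(goldtigs):
        rec.name = f"goldtig_{i}"
    stats["silver_bases"] = silver_bases
    stats["golden_bases"] = sum(len(r.seq) for r in goldtigs)
    stats["n_silver_paths"] = len(silver)
    stats["n_goldtigs"] = len(goldtigs)
    stats["window_queries"] = mibf.query_count
    return SelectionResult(silver_paths=silver, goldtigs=goldtigs, stats=stats)
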