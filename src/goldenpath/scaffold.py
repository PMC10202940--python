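"""Minimizer-based scaffolding of goldtigs with long-read evidence.

Goldtigs and reads are reduced to minimizer sketches (window minima of
canonical k-mer hashes). Reads are mapped to goldtigs through an index of
sketch minimizers that occur at exactly one goldtig position; mappings that
visit two or more goldtigs provide join evidence, accumulated in a scaffold
graph whose nodes are oriented goldtigs and whose directed edges carry a
support weight and a gap estimate (negative = putative overlap). A greedy
end-matching layout orders and orients the goldtigs; negative-gap joins are
resolved by overlap detection and trimming, non-negative gaps are filled
with bases from the best-supporting read. Subsequent rounds reuse the
original mappings lifted onto the new scaffold coordinates instead of
re-mapping the reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .hashing import canonical_kmer_hashes, encode, revcomp

logger = logging.getLogger(__name__)

_UMAX = np.uint64(0xFFFFFFFFFFFFFFFF)


@dataclass
class ChainParams:
    k: int = 32  # minimizer k for the main mapping
    w: int = 100  # minimizer window
    small_k: int = 15  # sensitive re-sketching (overlaps, gap-fill pass 2)
    small_w: int = 10
    min_edge_support: int = 2
    min_anchors: int = 3  # mappings with fewer anchors are discarded
    rounds: int = 5
    gap_fill: bool = True
    overlap_margin_factor: float = 1.5
    overlap_margin_add: int = 500
    # an overlap this deep relative to the shorter sequence means one
    # sequence is contained in the other; such pairs are not joined
    containment_frac: float = 0.75

    def __post_init__(self) -> None:
        if self.small_k >= self.k or self.small_w >= self.w:
            raise ValueError("small_k/small_w must be below k/w")
        if self.rounds < 1:
            raise ValueError("rounds >= 1 required")


# --- sketches ----------------------------------------------------------------


@dataclass(frozen=True)
class MinimizerSketch:
    """Ordered window-minimum minimizers of one sequence."""

    pos: np.ndarray  # k-mer start positions, strictly increasing
    hash: np.ndarray  # canonical 64-bit hashes
    fwd: np.ndarray  # True where the forward k-mer is the canonical strand

    def __len__(self) -> int:
        return len(self.pos)


def _forward_flags(codes: np.ndarray, starts: np.ndarray, k: int) -> np.ndarray:
    c = np.where(codes == 255, 0, codes).astype(np.uint64)
    fwd = np.zeros(len(starts), dtype=np.uint64)
    rc = np.zeros(len(starts), dtype=np.uint64)
    with np.errstate(over="ignore"):
        for j in range(k):
            col = c[starts + j]
            fwd += col << np.uint64(2 * (k - 1 - j))
            rc += (np.uint64(3) - col) << np.uint64(2 * j)
    return fwd <= rc


def sketch(seq: str, k: int, w: int) -> MinimizerSketch:
    """Window-minimum minimizer sketch (ties to the leftmost position).

    Every length-``w`` window of k-mer start positions contributes its
    minimum canonical hash; k-mers containing N never win a window. A
    sequence shorter than ``k`` yields an empty sketch.
    """
    codes = encode(seq)
    h, valid = canonical_kmer_hashes(codes, k)
    if len(h) == 0:
        empty = np.zeros(0, dtype=np.int64)
        return MinimizerSketch(empty, np.zeros(0, dtype=np.uint64),
                               np.zeros(0, dtype=bool))
    h = np.where(valid, h, _UMAX)
    if w <= 1:
        sel = np.flatnonzero(h != _UMAX)
    elif len(h) <= w:  # fewer k-mers than one window: one minimum
        cand = np.flatnonzero(h != _UMAX)
        if len(cand) == 0:
            sel = np.zeros(0, dtype=np.int64)
        else:
            sel = cand[[int(np.argmin(h[cand]))]]
    else:
        win = np.lib.stride_tricks.sliding_window_view(h, w)
        sel = np.unique(win.argmin(axis=1) + np.arange(len(h) - w + 1))
        sel = sel[h[sel] != _UMAX]
    pos = sel.astype(np.int64)
    return MinimizerSketch(pos, h[pos], _forward_flags(codes, pos, k))


# --- mapping -----------------------------------------------------------------


@dataclass(frozen=True)
class Mapping:
    """One chained read-to-goldtig mapping (the "verbose" record)."""

    read: str
    tig: str
    strand: str  # '+' or '-' (read strand relative to the goldtig)
    rpos: np.ndarray  # anchor k-mer starts on the read, increasing
    tpos: np.ndarray  # matching k-mer starts on the goldtig

    @property
    def n_anchors(self) -> int:
        return len(self.rpos)


def build_index(
    tigs: dict[str, str], params: ChainParams, per_tig_unique: bool = False
) -> dict[int, list[tuple[str, int, bool]]]:
    """Minimizer index: hash -> [(tig, pos, fwd), ...].

    By default a hash occurring at more than one goldtig position anywhere
    is dropped (repeat suppression for scaffolding). With
    ``per_tig_unique=True`` the uniqueness requirement applies within each
    goldtig only, so sequence shared between overlapping goldtigs still
    anchors reads to each of them — the mode used when gathering reads for
    polishing, where overlapping goldtigs are expected.
    """
    sketches = {name: sketch(s, params.k, params.w) for name, s in tigs.items()}
    index: dict[int, list[tuple[str, int, bool]]] = {}
    for name in sorted(sketches):
        sk = sketches[name]
        hashes, counts = np.unique(sk.hash, return_counts=True)
        tig_once = set(hashes[counts == 1].tolist())
        for p, h, f in zip(sk.pos.tolist(), sk.hash.tolist(), sk.fwd.tolist()):
            if h in tig_once:
                index.setdefault(h, []).append((name, p, f))
    if not per_tig_unique:
        index = {h: occ for h, occ in index.items() if len(occ) == 1}
    return index


def _longest_increasing(values: Sequence[int]) -> list[int]:
    """Indices of a longest strictly increasing subsequence (leftmost ties)."""
    tails: list[int] = []  # index into values of the tail of each length
    prev = [-1] * len(values)
    import bisect

    keys: list[int] = []
    for i, v in enumerate(values):
        j = bisect.bisect_left(keys, v)
        if j == len(keys):
            keys.append(v)
            tails.append(i)
        else:
            keys[j] = v
            tails[j] = i
        prev[i] = tails[j - 1] if j > 0 else -1
    out: list[int] = []
    i = tails[-1] if tails else -1
    while i >= 0:
        out.append(i)
        i = prev[i]
    return out[::-1]


def map_read(
    index: dict[int, tuple[str, int, bool]],
    read_name: str,
    seq: str,
    params: ChainParams,
) -> list[Mapping]:
    """Chained collinear mappings of one read against the goldtig index.

    Hits are grouped per goldtig; within a group the longest
    strand-consistent subset with monotone positions is kept (longest
    increasing subsequence of goldtig positions along the read). Mappings
    with fewer than ``min_anchors`` anchors are discarded.
    """
    rsk = sketch(seq, params.k, params.w)
    per_tig: dict[str, list[tuple[int, int, bool]]] = {}
    for p, h, f in zip(rsk.pos.tolist(), rsk.hash.tolist(), rsk.fwd.tolist()):
        for tig, tp, tf in index.get(h, ()):
            per_tig.setdefault(tig, []).append((p, tp, f == tf))
    out: list[Mapping] = []
    for tig in sorted(per_tig):
        hits = per_tig[tig]  # already in read order
        best: tuple[int, str, list[tuple[int, int]]] | None = None
        for strand in "+-":
            sub = [(rp, tp) for rp, tp, same in hits if same == (strand == "+")]
            if len(sub) < params.min_anchors:
                continue
            vals = [tp if strand == "+" else -tp for _, tp in sub]
            keep = _longest_increasing(vals)
            chain = [sub[i] for i in keep]
            if len(chain) >= params.min_anchors and (
                best is None or len(chain) > best[0]
            ):
                best = (len(chain), strand, chain)
        if best is not None:
            _, strand, chain = best
            rp = np.array([a for a, _ in chain], dtype=np.int64)
            tp = np.array([b for _, b in chain], dtype=np.int64)
            out.append(Mapping(read_name, tig, strand, rp, tp))
    return out


def map_all_reads(
    index: dict[int, tuple[str, int, bool]],
    reads: dict[str, str],
    params: ChainParams,
) -> dict[str, list[Mapping]]:
    return {
        name: maps
        for name, seq in reads.items()
        if (maps := map_read(index, name, seq, params))
    }


# --- scaffold graph ----------------------------------------------------------


def _flip(o: str) -> str:
    return "-" if o == "+" else "+"


@dataclass
class EdgeData:
    weight: int = 0
    gaps: list[float] = field(default_factory=list)
    # (read, mapping_left, mapping_right, stored_in_canonical_direction)
    supports: list[tuple[str, Mapping, Mapping]] = field(default_factory=list)

    @property
    def gap_est(self) -> float:
        return float(np.mean(self.gaps)) if self.gaps else 0.0


@dataclass
class ScaffoldGraph:
    """Directed oriented-goldtig graph; each edge stored once, canonically.

    The canonical key of edge (u, ou) -> (v, ov) is the lexicographic
    minimum of itself and its reverse-complement mirror
    (v, ~ov) -> (u, ~ou), which always exists and agrees by construction.
    """

    edges: dict[tuple[str, str, str, str], EdgeData] = field(
        default_factory=dict
    )

    @staticmethod
    def canonical(key: tuple[str, str, str, str]) -> tuple[str, str, str, str]:
        u, ou, v, ov = key
        mirror = (v, _flip(ov), u, _flip(ou))
        return min(key, mirror)

    def summary(self) -> dict[tuple[str, str, str, str], int]:
        return {k: e.weight for k, e in self.edges.items()}


def _junction_gap(
    mu: Mapping, mv: Mapping, len_u: int, len_v: int, k: int
) -> float:
    """Gap estimate between oriented u and v from one spanning read."""
    ra, ta = int(mu.rpos[-1]), int(mu.tpos[-1])
    rb, tb = int(mv.rpos[0]), int(mv.tpos[0])
    flank_u = (len_u - (ta + k)) if mu.strand == "+" else ta
    flank_v = tb if mv.strand == "+" else (len_v - (tb + k))
    return (rb - (ra + k)) - flank_u - flank_v


def build_graph(
    mappings: dict[str, list[Mapping]],
    tig_lengths: dict[str, int],
    params: ChainParams,
) -> ScaffoldGraph:
    """Scaffold graph from reads whose mappings span several goldtigs.

    Each consecutive oriented pair visited by a read adds one unit of edge
    weight and one per-read gap estimate (mean aggregated); edges below
    ``min_edge_support`` are dropped.
    """
    graph = ScaffoldGraph()
    for read in sorted(mappings):
        maps = sorted(mappings[read], key=lambda m: int(m.rpos[0]))
        for mu, mv in zip(maps, maps[1:]):
            if mu.tig == mv.tig:
                continue
            key = (mu.tig, mu.strand, mv.tig, mv.strand)
            ck = ScaffoldGraph.canonical(key)
            data = graph.edges.setdefault(ck, EdgeData())
            data.weight += 1
            data.gaps.append(
                _junction_gap(mu, mv, tig_lengths[mu.tig],
                              tig_lengths[mv.tig], params.k)
            )
            if ck == key:
                data.supports.append((read, mu, mv))
            else:
                data.supports.append((read, mv, mu))  # stored mirrored
    def _keep(key: tuple[str, str, str, str], d: EdgeData) -> bool:
        if d.weight < params.min_edge_support:
            return False
        shorter = min(tig_lengths[key[0]], tig_lengths[key[2]])
        # deeply negative gap = containment, not a resolvable end overlap
        return d.gap_est > -params.containment_frac * shorter

    graph.edges = {k: d for k, d in graph.edges.items() if _keep(k, d)}
    return graph


# --- layout ------------------------------------------------------------------


def layout(
    graph: ScaffoldGraph, tig_names: Iterable[str]
) -> list[list[tuple[str, str]]]:
    """Greedy end-matching layout.

    Edges are taken by descending weight (ties: smaller |gap|, then
    lexicographic key); an edge is accepted iff both incident goldtig ends
    are unused and it closes no cycle. Every goldtig appears exactly once
    across the emitted paths (singletons included).
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def end_of(node: str, orient: str, side: str) -> tuple[str, str]:
        # the physical end of `node` used when traversing it with `orient`:
        # side 'out' = end facing the next node, 'in' = facing the previous
        if side == "out":
            return (node, "R" if orient == "+" else "L")
        return (node, "L" if orient == "+" else "R")

    used: set[tuple[str, str]] = set()
    links: dict[tuple[str, str], tuple[str, str]] = {}  # end <-> end
    order = sorted(
        graph.edges.items(),
        key=lambda kv: (-kv[1].weight, abs(kv[1].gap_est), kv[0]),
    )
    for (u, ou, v, ov), _data in order:
        eu = end_of(u, ou, "out")
        ev = end_of(v, ov, "in")
        if eu in used or ev in used or find(u) == find(v):
            continue
        used.add(eu)
        used.add(ev)
        parent[find(u)] = find(v)
        links[eu] = ev
        links[ev] = eu

    def other(end: tuple[str, str]) -> tuple[str, str]:
        return (end[0], "R" if end[1] == "L" else "L")

    paths: list[list[tuple[str, str]]] = []
    visited: set[str] = set()
    for start in sorted(tig_names):
        if start in visited:
            continue
        # walk backward (entry end to entry end) to the path's terminal node
        end = (start, "L")  # entry end when traversing `start` as '+'
        steps = 0
        while end in links:
            end = other(links[end])
            steps += 1
            assert steps <= len(links), "cycle in layout links"
        # traverse forward from the terminal: entering a node at its L end
        # means '+' orientation, at its R end means '-'
        path: list[tuple[str, str]] = []
        while True:
            node, side = end
            path.append((node, "+" if side == "L" else "-"))
            visited.add(node)
            out = other(end)
            if out not in links:
                break
            end = links[out]
        paths.append(path)
    return paths


# --- overlap resolution -------------------------------------------------------


def _unique_sketch(seq: str, params: ChainParams) -> dict[int, int]:
    """hash -> position for multiplicity-1 minimizers at (small_k, small_w)."""
    sk = sketch(seq, params.small_k, params.small_w)
    hashes, counts = np.unique(sk.hash, return_counts=True)
    once = set(hashes[counts == 1].tolist())
    return {
        h: p for h, p in zip(sk.hash.tolist(), sk.pos.tolist()) if h in once
    }


def detect_overlap(
    left: str, right: str, gap_est: float, params: ChainParams
) -> tuple[int, int] | None:
    """Trim coordinates resolving a putative overlap (negative gap estimate).

    The terminal regions (|gap| scaled by a safety margin) of both sequences
    are sketched at (small_k, small_w); multiplicity-1 minimizers form an
    undirected graph whose edges are sketch adjacencies weighted by the
    number of sequences sharing them. Weight-2 edges leave linear paths;
    the middle minimizer of the longest path anchors the two sequences.

    Returns ``(cut_left, cut_right)`` meaning keep ``left[:cut_left]`` and
    ``right[cut_right:]`` (the anchor bases appear exactly once), or None
    when no overlap is found.
    """
    if gap_est >= 0:
        raise ValueError("overlap detection requires a negative gap estimate")
    region = int(
        params.overlap_margin_factor * abs(gap_est) + params.overlap_margin_add
    )
    l_off = max(0, len(left) - region)
    lmap = _unique_sketch(left[l_off:], params)
    rmap = _unique_sketch(right[:region], params)

    graph = nx.Graph()
    for posmap in (lmap, rmap):
        ordered = sorted(posmap.items(), key=lambda kv: kv[1])
        for (h1, _), (h2, _) in zip(ordered, ordered[1:]):
            if h1 == h2:
                continue
            if graph.has_edge(h1, h2):
                graph[h1][h2]["weight"] += 1
            else:
                graph.add_edge(h1, h2, weight=1)
    keep = [(a, b) for a, b, d in graph.edges(data=True) if d["weight"] == 2]
    sub = graph.edge_subgraph(keep).copy() if keep else nx.Graph()

    best_path: list[int] | None = None
    for comp in nx.connected_components(sub):
        cg = sub.subgraph(comp)
        degs = dict(cg.degree())
        if max(degs.values()) > 2 or cg.number_of_edges() != len(comp) - 1:
            continue  # branching or cyclic component: not a linear mapping
        ends = sorted(n for n, d in degs.items() if d == 1)
        if not ends:
            continue
        path = [ends[0]]
        prev = None
        while True:
            nbrs = [n for n in cg.neighbors(path[-1]) if n != prev]
            if not nbrs:
                break
            prev = path[-1]
            path.append(nbrs[0])
        if best_path is None or len(path) > len(best_path):
            best_path = path
    if best_path is None:
        return None
    anchor = best_path[len(best_path) // 2]
    cut_left = l_off + lmap[anchor] + params.small_k
    cut_right = rmap[anchor] + params.small_k
    return cut_left, cut_right


# --- gap filling --------------------------------------------------------------


@dataclass(frozen=True)
class FillCandidate:
    """One join-supporting read, oriented to the scaffold direction."""

    name: str
    mean_anchors: float
    seq: str  # read sequence, reverse-complemented when needed
    # pass-1 fallback anchors, in oriented coordinates:
    left_anchor: tuple[int, int]  # (pos in left seq, pos in read)
    right_anchor: tuple[int, int]  # (pos in right seq, pos in read)
    k: int  # anchor k-mer size of the fallback anchors


def _match_chain(
    read_map: dict[int, int], flank_map: dict[int, int]
) -> list[tuple[int, int]] | None:
    """Shared-minimizer chain (read_pos, flank_pos); None when ambiguous."""
    common = sorted(
        ((read_map[h], fp) for h, fp in flank_map.items() if h in read_map),
    )
    if not common:
        return None
    fps = [fp for _, fp in common]
    if any(b <= a for a, b in zip(fps, fps[1:])):
        return None  # not a single collinear chain
    return common


def fill_gap(
    left: str,
    right: str,
    gap_est: float,
    candidates: Sequence[FillCandidate],
    params: ChainParams,
) -> tuple[int, str, int] | None:
    """Fill a non-negative gap with bases from the best-supporting read.

    Candidates are ranked by mean pass-1 anchor count over the two flanks
    (ties to the lexicographically smaller read name). The winner is
    re-sketched against the flanking regions at (small_k, small_w); if both
    pass-2 mappings are unambiguous, the anchors nearest the facing ends are
    the cut points, otherwise the stored pass-1 anchors are used. Returns
    ``(cut_left, gap_seq, cut_right)`` such that the joined sequence is
    ``left[:cut_left] + gap_seq + right[cut_right:]``, or None when no
    usable anchors exist.
    """
    if not candidates:
        return None
    winner = min(candidates, key=lambda c: (-c.mean_anchors, c.name))
    flank = max(1000, int(gap_est) + 1000)
    l_off = max(0, len(left) - flank)
    rlen = min(len(right), flank)

    rmap = _unique_sketch(winner.seq, params)
    chain_l = _match_chain(rmap, _unique_sketch(left[l_off:], params))
    chain_r = _match_chain(rmap, _unique_sketch(right[:rlen], params))

    if chain_l and chain_r:
        k2 = params.small_k
        rl, fl = max(chain_l, key=lambda rc: rc[1])  # nearest the left end
        rr, fr = min(chain_r, key=lambda rc: rc[1])  # nearest the right start
        cut_left = l_off + fl + k2
        cut_right = fr
        r_start, r_end = rl + k2, rr
    else:
        (fl, rl), (fr, rr) = winner.left_anchor, winner.right_anchor
        cut_left = fl + winner.k
        cut_right = fr
        r_start, r_end = rl + winner.k, rr
    if r_start <= r_end:
        return cut_left, winner.seq[r_start:r_end], cut_right
    # anchors overlap in the read (gap ~ 0): shift the right cut instead
    shift = r_start - r_end
    if cut_right + shift <= len(right):
        return cut_left, "", cut_right + shift
    return None


# --- liftover and rounds ------------------------------------------------------


@dataclass(frozen=True)
class Placement:
    """Where one source sequence ended up inside a scaffold."""

    scaffold: str
    offset: int  # scaffold position of oriented keep_start
    orient: str
    keep_start: int  # kept range in *oriented* source coordinates
    keep_end: int
    source_len: int


def liftover(
    mappings: dict[str, list[Mapping]],
    placements: dict[str, Placement],
    params: ChainParams,
) -> dict[str, list[Mapping]]:
    """Map anchors from source-sequence coordinates to scaffold coordinates.

    Anchors falling in trimmed-away regions are dropped; mappings left with
    fewer than ``min_anchors`` anchors are discarded.
    """
    out: dict[str, list[Mapping]] = {}
    k = params.k
    for read, maps in mappings.items():
        lifted: list[Mapping] = []
        for m in maps:
            pl = placements.get(m.tig)
            if pl is None:
                continue
            if pl.orient == "+":
                opos = m.tpos
                strand = m.strand
            else:
                opos = pl.source_len - k - m.tpos
                strand = _flip(m.strand)
            ok = (opos >= pl.keep_start) & (opos + k <= pl.keep_end)
            if int(ok.sum()) < params.min_anchors:
                continue
            rp = m.rpos[ok]
            sp = pl.offset + (opos[ok] - pl.keep_start)
            order = np.argsort(rp, kind="stable")
            lifted.append(Mapping(read, pl.scaffold, strand,
                                  rp[order], sp[order]))
        if lifted:
            out[read] = lifted
    return out


def _oriented(seq: str, orient: str) -> str:
    return seq if orient == "+" else revcomp(seq)


def _edge_for(
    graph: ScaffoldGraph, u: str, ou: str, v: str, ov: str
) -> tuple[EdgeData, bool]:
    """Edge data for the oriented pair, and whether it is stored as given."""
    key = (u, ou, v, ov)
    ck = ScaffoldGraph.canonical(key)
    return graph.edges[ck], ck == key


def _fill_candidates(
    data: EdgeData,
    as_stored: bool,
    ou: str,
    ov: str,
    left_pl: Placement,
    left_src_len: int,
    right_src_len: int,
    reads: dict[str, str],
    params: ChainParams,
) -> list[FillCandidate]:
    """Build oriented fill candidates for one junction.

    Anchors on the left goldtig are globalized to the growing scaffold via
    its placement; the right goldtig still has local oriented coordinates.
    """
    k = params.k
    cands: list[FillCandidate] = []
    for read, sa, sb in data.supports:
        mu, mv = (sa, sb) if as_stored else (sb, sa)
        rel = "+" if mu.strand == ou else "-"
        if ("+" if mv.strand == ov else "-") != rel:
            continue  # inconsistent orientation across the junction
        seq = reads.get(read)
        if seq is None:
            continue
        rseq = _oriented(seq, rel)
        rlen = len(seq)

        def o_read(rp: int) -> int:
            return rp if rel == "+" else rlen - k - rp

        def o_tig(tp: int, o: str, slen: int) -> int:
            return tp if o == "+" else slen - k - tp

        # anchor nearest the junction on each side, in oriented read coords
        iu = int(np.argmax([o_read(int(r)) for r in mu.rpos]))
        iv = int(np.argmin([o_read(int(r)) for r in mv.rpos]))
        lpos = o_tig(int(mu.tpos[iu]), ou, left_src_len)
        if not (left_pl.keep_start <= lpos <= left_pl.keep_end - k):
            continue  # anchor fell in a trimmed-away region
        la = (
            left_pl.offset + (lpos - left_pl.keep_start),
            o_read(int(mu.rpos[iu])),
        )
        ra = (
            o_tig(int(mv.tpos[iv]), ov, right_src_len),
            o_read(int(mv.rpos[iv])),
        )
        cands.append(
            FillCandidate(
                name=read,
                mean_anchors=(mu.n_anchors + mv.n_anchors) / 2.0,
                seq=rseq,
                left_anchor=la,
                right_anchor=ra,
                k=k,
            )
        )
    return cands


def _materialize(
    paths: list[list[tuple[str, str]]],
    seqs: dict[str, str],
    graph: ScaffoldGraph,
    reads: dict[str, str],
    params: ChainParams,
    round_no: int,
) -> tuple[dict[str, str], dict[str, Placement], dict[str, int]]:
    """Join each layout path into one scaffold sequence.

    Negative-gap junctions go through overlap detection and trimming (a
    single N when no overlap is found); non-negative gaps are filled from
    the best-supporting read when gap filling is on, else (or on failure)
    bridged with ``max(gap_est, 1)`` Ns.
    """
    scaffolds: dict[str, str] = {}
    placements: dict[str, Placement] = {}
    counts = {"joins": 0, "overlaps_trimmed": 0, "gaps_filled": 0,
              "n_joins_failed": 0}
    for pi, path in enumerate(paths):
        name = f"scaffold_r{round_no}_{pi}"
        first, o0 = path[0]
        cur = _oriented(seqs[first], o0)
        placements[first] = Placement(name, 0, o0, 0, len(cur), len(cur))
        prev_name, prev_orient = first, o0
        for tig, orient in path[1:]:
            sv = _oriented(seqs[tig], orient)
            data, as_stored = _edge_for(graph, prev_name, prev_orient,
                                        tig, orient)
            gap = data.gap_est
            joined = False
            if gap < 0:
                cut = detect_overlap(cur, sv, gap, params)
                if cut is not None:
                    cut_l, cut_r = cut
                    prev_pl = placements[prev_name]
                    if cut_l >= prev_pl.offset and cut_r < len(sv):
                        cur = cur[:cut_l] + sv[cut_r:]
                        placements[prev_name] = replace(
                            prev_pl,
                            keep_end=min(prev_pl.keep_end,
                                         prev_pl.keep_start + cut_l - prev_pl.offset),
                        )
                        placements[tig] = Placement(
                            name, cut_l, orient, cut_r, len(sv), len(sv)
                        )
                        counts["overlaps_trimmed"] += 1
                        joined = True
            else:
                if params.gap_fill:
                    prev_pl = placements[prev_name]
                    cands = _fill_candidates(
                        data, as_stored, prev_orient, orient,
                        prev_pl, len(seqs[prev_name]), len(sv), reads, params,
                    )
                    fill = fill_gap(cur, sv, gap, cands, params)
                    if fill is not None:
                        cut_l, mid, cut_r = fill
                        prev_pl = placements[prev_name]
                        if cut_l >= prev_pl.offset and cut_r < len(sv):
                            cur = cur[:cut_l] + mid + sv[cut_r:]
                            placements[prev_name] = replace(
                                prev_pl,
                                keep_end=min(
                                    prev_pl.keep_end,
                                    prev_pl.keep_start + cut_l - prev_pl.offset,
                                ),
                            )
                            placements[tig] = Placement(
                                name, cut_l + len(mid), orient,
                                cut_r, len(sv), len(sv),
                            )
                            counts["gaps_filled"] += 1
                            joined = True
            if not joined:
                n_run = max(int(round(gap)), 1)
                counts["n_joins_failed"] += 1
                placements[tig] = Placement(
                    name, len(cur) + n_run, orient, 0, len(sv), len(sv)
                )
                cur = cur + "N" * n_run + sv
            counts["joins"] += 1
            prev_name, prev_orient = tig, orient
        scaffolds[name] = cur
    return scaffolds, placements, counts


def run_rounds(
    tigs: dict[str, str],
    reads: dict[str, str],
    params: ChainParams,
) -> tuple[dict[str, str], dict]:
    """Iterative scaffolding: map once, then liftover between rounds.

    Round 1 maps the reads to the goldtigs; later rounds rebuild the
    scaffold graph from the lifted mappings without re-mapping. Stops early
    when a round makes no join.
    """
    index = build_index(tigs, params)
    mappings = map_all_reads(index, reads, params)
    seqs = dict(tigs)
    report: dict = {"rounds": []}
    for rnd in range(1, params.rounds + 1):
        lengths = {n: len(s) for n, s in seqs.items()}
        graph = build_graph(mappings, lengths, params)
        paths = layout(graph, seqs.keys())
        n_joins = sum(len(p) - 1 for p in paths)
        if n_joins == 0:
            report["rounds"].append({"round": rnd, "joins": 0})
            break
        seqs, placements, counts = _materialize(
            paths, seqs, graph, reads, params, rnd
        )
        mappings = liftover(mappings, placements, params)
        counts["round"] = rnd
        report["rounds"].append(counts)
    report["n_scaffolds"] = len(seqs)
    report["total_bases"] = sum(len(s) for s in seqs.values())
    return seqs, report


def write_verbose_mappings(mappings: dict[str, list[Mapping]], path) -> None:
    """Verbose mapping TSV: read, goldtig, strand, read_pos, tig_pos."""
    with open(path, "w") as out:
        out.write("read\tgoldtig\tstrand\tread_pos\ttig_pos\n")
        for read in sorted(mappings):
            for m in mappings[read]:
                for rp, tp in zip(m.rpos.tolist(), m.tpos.tolist()):
                    out.write(f"{read}\t{m.tig}\t{m.strand}\t{rp}\t{tp}\n")
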