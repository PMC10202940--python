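"""Synthetic data: genomes with controllable repeats, ONT-like long reads
with a per-read truth log, and a reference-based assembly scorer.

The generator emulates the input regime the pipeline is designed for:
reads of roughly 10-50 kbp drawn log-normally, per-read error rates around
4-12% split across mismatches, insertions and deletions, and quality
strings consistent with the simulated error rate (one constant Q per read,
which is all the mean-Phred read filter consumes). It does not model
pore-level signal, homopolymer-specific errors, or chimeric reads (a
chimera rate exists only to exercise graceful degradation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np

from .hashing import canonical_kmer_hashes, encode, revcomp
from .seqio import ReadRecord

_BASES = "ACGT"


@dataclass(frozen=True)
class RepeatSpec:
    unit_length: int
    copies: int
    identity: float = 1.0  # sequence identity of each pasted copy


@dataclass
class SimConfig:
    G: int = 1_000_000
    repeats: tuple[RepeatSpec, ...] = ()
    coverage: float = 20.0
    length_mean: float = 20_000.0  # log-normal, in bp
    length_sd: float = 8_000.0
    min_length: int = 1_000
    max_length: int = 50_000
    error_rate: float = 0.05  # per-read mean, split across sub/ins/del
    error_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)
    chimera_rate: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error rate must be in [0, 1)")
        if self.min_length < 1:
            raise ValueError("min read length must be >= 1")


@dataclass(frozen=True)
class ReadTruth:
    """Source interval, strand and injected errors of one read.

    ``errors`` are (position, type, base) triples expressed in the
    coordinates of the perfect (already strand-flipped) read at the moment
    of application, applied left to right; replaying them on the extracted
    interval reproduces the read byte-exactly.
    """

    name: str
    start: int
    end: int
    strand: str
    errors: tuple[tuple[int, str, str], ...]


@dataclass
class TruthLog:
    reads: dict[str, ReadTruth] = field(default_factory=dict)

    def replay(self, genome: str, name: str) -> str:
        tr = self.reads[name]
        perfect = genome[tr.start : tr.end]
        if tr.strand == "-":
            perfect = revcomp(perfect)
        return apply_errors(perfect, tr.errors)

    def write_tsv(self, path) -> None:
        with open(path, "w") as out:
            out.write("read\tstart\tend\tstrand\terrors\n")
            for tr in self.reads.values():
                err = ";".join(f"{p}:{t}:{b}" for p, t, b in tr.errors)
                out.write(f"{tr.name}\t{tr.start}\t{tr.end}\t{tr.strand}\t{err}\n")


def apply_errors(perfect: str, errors) -> str:
    """Apply (pos, type, base) edits left to right to a perfect read."""
    out: list[str] = []
    prev = 0
    for pos, etype, base in errors:
        out.append(perfect[prev:pos])
        if etype == "sub":
            out.append(base)
            prev = pos + 1
        elif etype == "ins":
            out.append(perfect[pos] + base)  # insertion after pos
            prev = pos + 1
        elif etype == "del":
            prev = pos + 1
        else:
            raise ValueError(f"unknown error type {etype!r}")
    out.append(perfect[prev:])
    return "".join(out)


def gen_genome(config: SimConfig) -> str:
    """Uniform i.i.d. genome with repeat units pasted at stated identity."""
    if config.G < 1000:
        raise ValueError("genome size must be at least 1000 bp")
    repeat_bases = sum(r.unit_length * r.copies for r in config.repeats)
    if repeat_bases > config.G:
        raise ValueError("repeat bases exceed the genome size")
    rng = np.random.Generator(np.random.PCG64(config.seed))
    codes = rng.integers(0, 4, size=config.G, dtype=np.uint8)
    cursor = 0
    for spec in config.repeats:
        unit = rng.integers(0, 4, size=spec.unit_length, dtype=np.uint8)
        for _ in range(spec.copies):
            copy = unit.copy()
            n_mut = rng.binomial(spec.unit_length, 1.0 - spec.identity)
            if n_mut:
                pos = rng.choice(spec.unit_length, size=n_mut, replace=False)
                copy[pos] = (copy[pos] + rng.integers(1, 4, size=n_mut)) % 4
            codes[cursor : cursor + spec.unit_length] = copy
            cursor += spec.unit_length
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def quality_char(error_rate: float) -> str:
    q = 50 if error_rate <= 0 else min(50, round(-10 * math.log10(error_rate)))
    return chr(33 + q)


def sim_reads(
    genome: str, config: SimConfig
) -> tuple[list[ReadRecord], TruthLog]:
    """Simulate reads until the total length reaches coverage x G.

    Lengths are log-normal (parametrised by mean/sd in bp, clipped to
    [min_length, max_length]); starts are uniform; strands Bernoulli(0.5);
    errors are injected per read at the configured rate and mix and recorded
    in the truth log; the quality string is the constant
    Q = round(-10 log10(error_rate)).
    """
    rng = np.random.Generator(np.random.PCG64(config.seed + 0x5EED))
    target = config.coverage * len(genome)
    mu = math.log(
        config.length_mean**2
        / math.sqrt(config.length_mean**2 + config.length_sd**2)
    )
    sigma = math.sqrt(math.log(1 + (config.length_sd / config.length_mean) ** 2))
    qchar = quality_char(config.error_rate)
    mix = np.array(config.error_mix, dtype=float)
    mix = mix / mix.sum()

    reads: list[ReadRecord] = []
    log = TruthLog()
    total = 0
    i = 0
    while total < target:
        length = int(np.clip(rng.lognormal(mu, sigma),
                             config.min_length, config.max_length))
        length = min(length, len(genome))
        start = int(rng.integers(0, len(genome) - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        perfect = genome[start : start + length]
        if strand == "-":
            perfect = revcomp(perfect)
        n_err = rng.binomial(length, config.error_rate)
        if n_err:
            pos = np.sort(rng.choice(length, size=n_err, replace=False))
            kinds = rng.choice(3, size=n_err, p=mix)
            errors = []
            for p, kd in zip(pos.tolist(), kinds.tolist()):
                if kd == 0:
                    cur = perfect[p]
                    alt = _BASES[(_BASES.index(cur) + int(rng.integers(1, 4))) % 4] \
                        if cur in _BASES else "A"
                    errors.append((p, "sub", alt))
                elif kd == 1:
                    if p == length - 1:
                        continue  # insertion-after needs a following anchor
                    errors.append((p, "ins", _BASES[int(rng.integers(0, 4))]))
                else:
                    errors.append((p, "del", ""))
            errors = tuple(errors)
        else:
            errors = ()
        seq = apply_errors(perfect, errors)
        name = f"read_{i}"
        reads.append(ReadRecord(name=name, seq=seq, qual=qchar * len(seq)))
        log.reads[name] = ReadTruth(name, start, start + length, strand, errors)
        total += length
        i += 1
    return reads, log


# --- assembly scoring --------------------------------------------------------


@dataclass(frozen=True)
class AssemblyScore:
    genome_fraction: float  # covered genome bases / G
    mean_identity: float  # alignment identity, weighted by aligned length
    misjoins: int


def _unique_kmer_index(genome: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sorted canonical hashes of genome k-mers occurring exactly once,
    with their positions and forward-strand flags."""
    codes = encode(genome)
    h, valid = canonical_kmer_hashes(codes, k)
    pos = np.flatnonzero(valid)
    h = h[valid]
    order = np.argsort(h, kind="stable")
    hs, ps = h[order], pos[order]
    uniq_mask = np.ones(len(hs), dtype=bool)
    dup = hs[1:] == hs[:-1]
    uniq_mask[1:] &= ~dup
    uniq_mask[:-1] &= ~dup
    hs, ps = hs[uniq_mask], ps[uniq_mask]
    # strand flag: True when the forward k-mer is the canonical one
    fwd = _forward_is_canonical(codes, ps, k)
    return hs, ps, fwd


def _forward_is_canonical(codes: np.ndarray, starts: np.ndarray, k: int) -> np.ndarray:
    c = np.where(codes == 255, 0, codes).astype(np.uint64)
    fwd = np.zeros(len(starts), dtype=np.uint64)
    rc = np.zeros(len(starts), dtype=np.uint64)
    with np.errstate(over="ignore"):
        for j in range(k):
            col = c[starts + j]
            fwd += col << np.uint64(2 * (k - 1 - j))
            rc += (np.uint64(3) - col) << np.uint64(2 * j)
    return fwd <= rc


def score_assembly(
    assembly: dict[str, str],
    genome: str,
    k: int = 32,
    min_anchors: int = 5,
    misjoin_slack: int = 10_000,
) -> AssemblyScore:
    """Anchor each assembly sequence to the known genome and score it.

    Unique exact k-mer matches seed collinear segments; each segment is
    aligned (edlib, global) to its genome interval for identity. Coverage is
    the union of segment genome intervals over G. A misjoin is a pair of
    adjacent segments >=1 kb each within one assembly sequence that map more
    than ``misjoin_slack`` apart, out of order, or in conflicting
    orientation.
    """
    hs, ps, fwd = _unique_kmer_index(genome, k)
    intervals: list[tuple[int, int]] = []
    total_len = 0
    total_dist = 0
    misjoins = 0

    for seq in assembly.values():
        codes = encode(seq)
        h, valid = canonical_kmer_hashes(codes, k)
        apos = np.flatnonzero(valid)
        h = h[valid]
        loc = np.searchsorted(hs, h)
        if len(hs):
            loc_c = np.minimum(loc, len(hs) - 1)
            hitmask = (loc < len(hs)) & (hs[loc_c] == h)
        else:
            loc_c = loc
            hitmask = np.zeros(len(h), dtype=bool)
        a = apos[hitmask]
        g = ps[loc_c[hitmask]]
        gf = fwd[loc_c[hitmask]]
        af = _forward_is_canonical(codes, a, k)
        same = gf == af  # + orientation when both strands agree
        # split anchor list (ordered by assembly position) into collinear runs
        segments: list[tuple[int, int, int, int, bool]] = []
        si = None
        for idx in range(len(a)):
            if si is None:
                si = idx
                continue
            ok = (
                same[idx] == same[si]
                and a[idx] - a[idx - 1] < 5000
                and abs(
                    (g[idx] - g[idx - 1])
                    - (a[idx] - a[idx - 1]) * (1 if same[idx] else -1)
                )
                <= 200
            )
            if not ok:
                if idx - si >= min_anchors:
                    segments.append(_seg(a, g, same, si, idx, k))
                si = idx
        if si is not None and len(a) - si >= min_anchors:
            segments.append(_seg(a, g, same, si, len(a), k))

        for (a0, a1, g0, g1, plus) in segments:
            sub = seq[a0:a1]
            ref = genome[g0:g1]
            if not plus:
                ref = revcomp(ref)
            res = edlib.align(sub, ref, mode="NW", task="distance")
            total_dist += res["editDistance"]
            total_len += max(len(sub), len(ref))
            intervals.append((g0, g1))
        big = [s for s in segments if s[1] - s[0] >= 1000]
        for prev, cur in zip(big, big[1:]):
            if prev[4] != cur[4]:
                misjoins += 1
                continue
            gap_a = cur[0] - prev[1]
            gap_g = (cur[2] - prev[3]) if prev[4] else (prev[2] - cur[3])
            if abs(gap_g - gap_a) > misjoin_slack:
                misjoins += 1

    covered = 0
    if intervals:
        intervals.sort()
        cs, ce = intervals[0]
        for s, e in intervals[1:]:
            if s > ce:
                covered += ce - cs
                cs, ce = s, e
            else:
                ce = max(ce, e)
        covered += ce - cs
    frac = covered / len(genome)
    identity = 0.0 if total_len == 0 else 1.0 - total_dist / total_len
    return AssemblyScore(genome_fraction=frac, mean_identity=identity,
                         misjoins=misjoins)


def _seg(a, g, same, si, sj, k) -> tuple[int, int, int, int, bool]:
    plus = bool(same[si])
    a0, a1 = int(a[si]), int(a[sj - 1]) + k
    if plus:
        g0, g1 = int(g[si]), int(g[sj - 1]) + k
    else:
        g0, g1 = int(g[sj - 1]), int(g[si]) + k
    return (a0, a1, g0, g1, plus)
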