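# Methods

## The golden-path model

`goldenpath` assembles long, erroneous reads without any all-vs-all overlap
step. The working assumption is that at modest coverage (≥ ~10X) a genome
can be represented by a *tiling subset* of the reads themselves — a "golden
path" of roughly 1X — and that such a subset can be selected in a single
streaming pass per round by asking, read by read: *does this read cover
genome not yet in the path?* Membership is decided with a dynamic
multi-index Bloom filter (miBf) keyed by spaced-seed k-mers, so the cost per
read is proportional to its length and the whole selection is linear in
total read bases. The selected sequences are raw reads (goldtigs), so their
base quality equals the read error rate; a targeted k-mer polishing stage
then corrects them, and a minimizer-sketch scaffolder orders, orients,
merges and gap-fills them into the final assembly.

Assumptions worth stating explicitly:

- reads are long enough that a t = 1000 bp tile contains hundreds of
  spaced-seed windows (the tally statistic needs that mass);
- per-base error is roughly uniform and ≤ ~12%; spaced seeds (18 care
  positions over a span of 31) tolerate mismatches at don't-care positions,
  giving a per-seed window match probability of ≈ (1−e)³⁶ between two
  independent ~e-error copies of the same locus — about 16% at e = 5%,
  i.e. hundreds of expected tally hits per tile, against a threshold of 10;
- coverage is high enough (~15X+) that k-mers of the genome recur across
  reads (the polishing filters require multiplicity ≥ 2 by default).

## Selection (golden path)

Pass 1 inserts the h = 3 spaced-seed hashes of every window of every
filter-passing read (length ≥ m, mean Phred > P) into a Bloom bit array of
2^p bits; the array is then frozen and a rank (popcount) index maps each set
bit to a slot in an ID array. Pass 2 streams the reads again: each read is
cut into t bp tiles, every window lying fully inside a tile is queried, and
the returned block IDs are tallied per tile. A tile is assigned when its
best ID's tally strictly exceeds x (default 10). Because consecutive blocks
of one inserted sequence carry consecutive IDs, neighbouring tiles of a
read that truly overlaps the path agree within ±1 ID — the refinement
sweep promotes an unassigned tile when its own tally table supports a
neighbour's ID ±1 with at least ⌈x/2⌉ hits, and demotes an isolated
assignment (> ±1 from every assigned neighbour) weaker than 2x. Reads then
resolve to skip / insert / trim-and-insert exactly as the tile pattern
dictates; trim keeps the longest unassigned run plus one assigned tile on
each existing side (ties to the leftmost run). Inserted sequence is
re-tiled, grouped into blocks of b = 10 tiles, given fresh consecutive
block IDs, and written into the ID array (newest write wins; there is no
collision rescue — the tally threshold absorbs occasional slot losses).

A silver path closes at G·r accumulated bases (r = 0.9); the ID array is
zeroed and the stream continues until M = 5 silver paths exist or reads run
out. The golden round runs the same loop over the concatenated silver
sequences to exhaustion. Two choices the description of the method leaves
open:

- **Shared bit array.** The Bloom bits and rank index are built once from
  the full filtered read set and shared by every silver path and by the
  golden round; only the ID array is reset. Silver sequences are verbatim
  substrings of pass-1 reads, so sharing preserves the no-false-negative
  guarantee while keeping memory flat.
- **Silver sequences bypass the m/P filter** in the golden round: they may
  be shorter than m after trimming and carry no quality strings. Sequences
  shorter than one tile are treated as a single tile so every selected base
  can still be emitted.

Bloom sizing: p defaults to ⌈log₂(40 × filtered bases)⌉ — ~40 bits per
probe-generating base keeps the per-probe false-positive rate under 1% at
h = 3, and a window only counts as present when all three bits are set.

## Polishing

Each goldtig gets one Bloom filter per k in (32, 28, 24, 20), holding the
canonical k-mers of the reads mapped to it — but only k-mers seen at least
`min_count = 2` times. The multiplicity cutoff is load-bearing: erroneous
read k-mers are overwhelmingly singletons while genomic k-mers recur across
the pile-up, and without the cutoff every error of every read (including
the goldtig's own source read) vouches for itself. For the same reason the
pipeline excludes a goldtig's source read from its own filter set.

The scan runs at each k from largest to smallest: a present→absent
transition of the draft's k-mer presence profile marks the suspect base
j = i + k − 1. A locus flagged at a large k is attempted only if the
smallest-k k-mer ending at j is also absent (coverage holes of the sparse
k = 32 filter would otherwise dominate the scan). Candidate edits are
tiered: substitutions and 1 bp indels first, then 2 bp and 3 bp variants —
including multi-base substitutions over seq[j:j+d], which are what repair
two errors closer than k apart (no single edit can ever assemble a fully
present window there). Each candidate is scored by its present k-mers over
the verify window (k k-mers for substitutions, 2k−1 for indels, clipped at
sequence ends) and must satisfy two conditions:

1. **witness** — the k-mer that ends at the edited base must itself be
   present; for insertions the witness is instead the k-mer spanning the
   whole insert *plus the junction base after it*. Without the junction
   form, an insertion can certify itself by merely extending the clean left
   context along the filter's de Bruijn graph, which cascades;
2. **support** — the score must reach max(min_support = 3, unedited score
   + 2), capped at the window size. The all-k-mers-present window is the
   strong special case; the margin-over-unedited form is what lets clusters
   of nearby errors peel open left-to-right over repeated rounds.

The best-scoring candidate wins (ties to the fixed candidate order:
substitutions, insertions A<C<G<T, deletion, per tier). Rounds repeat until
a full sweep makes no edit (cap 6). Unresolvable loci are left unchanged;
the cursor always advances, so termination is structural. The edit log
records (goldtig, position, type, before, after) in the coordinates of the
draft at application time; replaying it sequentially reproduces the output
exactly.

## Scaffolding

Goldtigs and reads are sketched with window-minimum minimizers (k = 32,
w = 100; ties to the leftmost position). The goldtig index drops minimizers
occurring at more than one goldtig position; read hits are chained per
goldtig by longest strictly-monotone subsequence, and mappings with < 3
anchors are dropped. Reads visiting ≥ 2 goldtigs contribute +1 weight to
each consecutive oriented pair with a per-read gap estimate
(read distance between junction anchors minus the unmapped goldtig flanks);
edges aggregate the mean gap and are dropped below weight 2 — or when the
gap estimate is deeper than 75% of the shorter sequence, which indicates
containment rather than a resolvable end overlap (the golden path
deliberately contains redundant sequence, and "resolving" a containment as
an overlap amputates the longer sequence).

Layout is greedy end-matching: edges by descending weight (ties: smaller
|gap|, then lexicographic key), accepted only if both incident contig ends
are free and no cycle forms; every goldtig appears exactly once across the
resulting paths.

Negative-gap junctions go through overlap detection: the terminal regions
(1.5·|gap| + 500 bp) are re-sketched at small_k = 15 / small_w = 10,
multiplicity-1 minimizers form a graph whose edges are sketch adjacencies
weighted by how many of the two sequences share them; weight-2 edges leave
linear paths, and the middle minimizer of the longest path anchors the cut
(the anchor k-mer appears exactly once in the join). If no path survives,
the junction gets a single N. Non-negative gaps are filled from the
supporting read with the highest mean pass-1 anchor count (ties to the
lexicographically smaller name), re-anchored against the flanks at
small_k/small_w (pass 2); if either flank's pass-2 chain is ambiguous the
stored pass-1 anchors serve as cut points, and failing that the gap becomes
max(gap, 1) Ns.

Subsequent rounds (default 5) reuse the round-1 mappings lifted through
each goldtig's placement (scaffold, offset, orientation, kept range;
anchors in trimmed regions dropped) instead of re-mapping, and stop early
on a join-free round.

For *polish-stage* read gathering (not scaffolding) the mapping uses denser
sketches (k = 20, w = 20) and per-goldtig multiplicity filtering: at 5%
draft and 5% read error the chance that both copies of a 32-mer are clean
is ~3.6%, too sparse to anchor reads on 2–5 kb goldtigs, and overlapping
goldtigs are expected rather than exceptional there.

## Synthetic data

The generator emulates the target input regime: uniform i.i.d. genomes with
optional pasted repeat units at a stated identity; log-normal read lengths
(mean 20 kb, sd 8 kb, clipped to [1, 50] kb); uniform start positions;
Bernoulli(1/2) strand; a per-read error rate (default 5%) split
40/30/30 across substitutions, insertions and deletions; and a constant
per-read quality Q = round(−10·log₁₀(error rate)) — per-base quality
variation is not modelled because the selection filter consumes only the
mean. Every read's source interval, strand and injected errors go to a
truth log whose replay reproduces the read byte-exactly.

What the generator does *not* model — and what passing tests therefore do
not demonstrate about real data: chimeric reads (an optional chimera rate
exists only to exercise degradation), homopolymer-biased or signal-level
error structure, non-uniform coverage, heterozygosity, and real repeat
architectures beyond simple pasted units. Positions within one read length
of the genome ends are undersampled (reads never start before 0), so
genome-fraction numbers on deliberately small test genomes run ~2–3%
below what the same pipeline achieves at the 1 Mb benchmark scale.

The built-in evaluator anchors assembly sequences to the known genome with
unique exact 32-mers, merges collinear anchor runs into segments, computes
identity by global alignment (edlib) of each segment against its genome
interval (length-weighted mean), coverage as the union of segment intervals
over G, and counts a misjoin for adjacent ≥1 kb segments of one sequence
that map > 10 kb apart, out of order, or in conflicting orientation.

## Parameters

| Parameter | Default | Units | Why |
|---|---|---|---|
| t (tile) | 1000 | bp | tally mass per tile vs locality of assignment |
| b (tiles/block) | 10 | tiles | one block ≈ one 10 kb locus |
| x (tally threshold) | 10 | hits | rejects Bloom/ID noise; strict ">" |
| m (min read length) | 20000 | bp | human-scale default; toy preset 5000 |
| P (min mean Phred) | 15 | Q | "higher than P"; toy preset 10 (5% reads are Q13) |
| r (silver coverage) | 0.9 | X | per-path base budget G·r |
| M (silver paths) | 5 | paths | union of subsamples covers the genome |
| p (Bloom log2 bits) | auto | bits | ⌈log₂(40·filtered bases)⌉, <1% FPR/probe |
| k_list (polish) | 32,28,24,20 | bp | specificity→sensitivity ladder |
| min_count | 2 | copies | singleton (erroneous) k-mers excluded |
| min_support | 3 | k-mers | candidate acceptance floor |
| max_indel | 3 | bp | candidate tier depth |
| k / w (map) | 32 / 100 | bp | scaffolding sketch density |
| small_k / small_w | 15 / 10 | bp | sensitive re-sketching at junctions |
| min_edge_support | 2 | reads | scaffold edge evidence |
| rounds | 5 | — | liftover-based scaffolding rounds |

## Numerical and procedural choices

- All coordinates are 0-based half-open; trailing sub-tile bases join the
  last tile so every base can be emitted.
- Ties break deterministically everywhere: smaller block ID at equal tally,
  leftmost unassigned run, leftmost window minimum, candidate order in
  polishing, lexicographic read name in gap filling, edge key order in
  layout. Reruns are byte-identical; nothing in the pipeline draws random
  numbers.
- Spaced seeds are palindromic (symmetric care masks), which is what makes
  strand-canonical hashing of masked windows well defined; windows
  containing N are skipped for hashing but still occupy tile coordinates.
- Hashing is a splitmix64 finalizer over 2-bit-packed canonical windows
  (the smaller of forward/reverse-complement codes, salted per seed).
- Degenerate inputs: empty FASTQ → "no usable reads" error; reads shorter
  than the seed span contribute nothing; goldtigs with no mapped reads pass
  through polishing unchanged (with a warning); gap estimates of exactly 0
  are treated as fillable gaps and resolve to exact junctions when a
  spanning read anchors both flanks.
- Benchmark problem sizes, chosen to exercise the stated study conditions
  at desk scale: 1 Mb genome at 20X / 5% error for selection-coverage and
  end-to-end measurements (seeds 1–3 for coverage), 500 kb at 10/20/40X
  for the query-linearity measurement, 100 kb fixtures for the miBf oracle,
  polishing, overlap, gap-fill and liftover checks.

## Known limitations

- The neighbour-refinement rule and its thresholds are this package's own
  concrete formulation of the tile-refinement idea; the operation is
  isolated behind `refine_assignments` so an alternative rule can be
  swapped in.
- Structural misassembly correction between polishing and scaffolding is an
  identity placeholder with a documented interface; chimeric reads
  therefore propagate (the generator produces none by default).
- Unresolved polishing loci are left unchanged, not soft-masked.
- Gap fills splice raw read bases, which carry read-level error; at the
  default conditions this affects a few kb per megabase.
- The scaffold layout is a greedy end-matching heuristic; it does not
  revisit choices, so a heavier spurious edge can displace a true join
  (mitigated by the weight, containment and cycle guards).
- Query-side miBf false positives are controlled (<1%/probe at 3 probes,
  all required) but not zero; the tally threshold x is the systemic guard.
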