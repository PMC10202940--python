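"""End-to-end pipeline: selection -> polishing -> scaffolding.

The stages run in a fixed order: golden-path selection builds the draft
goldtigs from the raw reads; targeted k-mer polishing corrects base errors
in each goldtig using the reads mapped to it; minimizer scaffolding orders,
orients, merges and gap-fills the polished goldtigs over several
liftover-based rounds. A structural-misassembly correction stage sits
between polishing and scaffolding as a documented no-op placeholder so an
external tool can be slotted in.

Reruns with the same configuration and inputs produce byte-identical
output; there is no hidden randomness in any stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .hashing import SpacedSeedSet, default_seeds
from .polish import PolishParams, polish_all, write_edit_log
from .scaffold import ChainParams, build_index, map_read, run_rounds, \
    write_verbose_mappings
from .seqio import ReadRecord, read_fastq, write_fasta
from .select import GoldPathParams, SelectionResult, build_paths

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Union of the stage parameters plus paths and toggles."""

    genome_size: int
    reads_path: str | None = None
    outdir: str | None = None
    seed: int = 1
    # selection
    t: int = 1000
    b: int = 10
    x: int = 10
    m: int = 20_000
    P: float = 15.0
    r: float = 0.9
    M: int = 5
    bf_bits: int | None = None  # log2 Bloom bits; None = auto
    seeds: SpacedSeedSet = field(default_factory=default_seeds)
    # polishing
    k_list: tuple[int, ...] = (32, 28, 24, 20)
    skip_polish: bool = False
    # scaffolding
    k: int = 32
    w: int = 100
    small_k: int = 15
    small_w: int = 10
    rounds: int = 5
    min_edge_support: int = 2
    gap_fill: bool = True

    def goldpath_params(self) -> GoldPathParams:
        return GoldPathParams(G=self.genome_size, t=self.t, b=self.b,
                              x=self.x, m=self.m, P=self.P, r=self.r,
                              M=self.M, seeds=self.seeds, p=self.bf_bits)

    def polish_params(self) -> PolishParams:
        return PolishParams(k_list=self.k_list)

    def chain_params(self) -> ChainParams:
        return ChainParams(k=self.k, w=self.w, small_k=self.small_k,
                           small_w=self.small_w, rounds=self.rounds,
                           min_edge_support=self.min_edge_support,
                           gap_fill=self.gap_fill)

    def polish_map_params(self) -> ChainParams:
        """Sensitive mapping for read-to-goldtig assignment before polishing.

        Polishing wants recall (every read covering a goldtig should feed
        its filters, including on short goldtigs), so the sketches are
        denser and the k-mers shorter than for scaffolding, where minimizer
        specificity matters more.
        """
        return ChainParams(k=20, w=20, small_k=15, small_w=10)


def toy_config(genome_size: int, **overrides) -> RunConfig:
    """Preset for small simulated genomes.

    The read-length floor is scaled to 5 kb (the stock 20 kb default assumes
    human-scale read sets) and the quality threshold to Q10, matching
    simulated error rates around 5% (Q13 reads); the stock threshold targets
    much cleaner data and would reject such read sets wholesale.
    """
    cfg = RunConfig(genome_size=genome_size, m=5000, P=10.0)
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


def correct_misassemblies(goldtigs: dict[str, str]) -> dict[str, str]:
    """Structural misassembly correction stage (placeholder interface).

    Chimeric-read induced misjoins would be cut here by an external tool
    that maps reads back to the goldtigs and splits them at spanning-
    coverage dropouts. The built-in implementation is the identity.
    """
    return goldtigs


@dataclass
class PipelineResult:
    goldtigs: dict[str, str]
    polished: dict[str, str]
    scaffolds: dict[str, str]
    selection: SelectionResult
    report: dict
    edits: list = field(default_factory=list)


def map_reads_to_goldtigs(
    goldtigs: dict[str, str],
    reads: dict[str, str],
    exclude_source: dict[str, str],
    chain: ChainParams,
) -> dict[str, list[str]]:
    """Read sequences mapped to each goldtig, for targeted polishing.

    Each goldtig's own source read is excluded from its set: a goldtig is a
    verbatim (trimmed) read, so its source would vouch for every one of its
    own errors and make them undetectable.
    """
    index = build_index(goldtigs, chain, per_tig_unique=True)
    mapped: dict[str, list[str]] = {name: [] for name in goldtigs}
    for rname in sorted(reads):
        for m in map_read(index, rname, reads[rname], chain):
            if exclude_source.get(m.tig) == rname:
                continue
            mapped[m.tig].append(reads[rname])
    return mapped


def run_pipeline(
    reads: Callable[[], Iterable[ReadRecord]] | Sequence[ReadRecord],
    config: RunConfig,
) -> PipelineResult:
    """Run selection, polishing and scaffolding in memory."""
    stream = reads if callable(reads) else (lambda: iter(reads))
    report: dict = {"config": {"genome_size": config.genome_size,
                               "seed": config.seed}}

    logger.info("stage 1/3: golden-path selection")
    selection = build_paths(stream, config.goldpath_params())
    goldtigs = {rec.name: rec.seq for rec in selection.goldtigs}
    provenance = {rec.name: rec.source_read for rec in selection.goldtigs}
    report["selection"] = selection.stats

    chain = config.chain_params()
    reads_dict = {rec.name: rec.seq for rec in stream()}

    if config.skip_polish:
        polished = dict(goldtigs)
        report["polish"] = {"skipped": True}
        edits = []
    else:
        logger.info("stage 2/3: targeted polishing")
        mapped = map_reads_to_goldtigs(
            goldtigs, reads_dict, provenance, config.polish_map_params()
        )
        polished, edits = polish_all(goldtigs, mapped, config.polish_params())
        report["polish"] = {
            "edits": len(edits),
            "goldtigs_without_reads": sum(1 for v in mapped.values() if not v),
        }
    polished = correct_misassemblies(polished)

    logger.info("stage 3/3: scaffolding (%d rounds max)", config.rounds)
    scaffolds, scaf_report = run_rounds(polished, reads_dict, chain)
    report["scaffold"] = scaf_report
    return PipelineResult(goldtigs, polished, scaffolds, selection, report,
                          edits)


def run(config: RunConfig) -> PipelineResult:
    """File-based pipeline run: read FASTQ, persist every stage's output."""
    if config.reads_path is None or config.outdir is None:
        raise ValueError("run() needs reads_path and outdir")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reads_path = config.reads_path

    result = run_pipeline(lambda: read_fastq(reads_path), config)

    for i, path in enumerate(result.selection.silver_paths):
        write_fasta(((r.name, r.seq) for r in path), outdir / f"path_{i}.fa")
    write_fasta(
        (
            (
                f"{r.name} read={r.source_read} "
                f"start={r.source_start} end={r.source_end}",
                r.seq,
            )
            for r in result.selection.goldtigs
        ),
        outdir / "goldtigs.fa",
    )
    write_fasta(result.polished.items(), outdir / "polished.fa")
    write_fasta(result.scaffolds.items(), outdir / "assembly.fa")
    write_edit_log(result.edits, outdir / "edits.tsv")
    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, default=str)
    return result
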