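"""Synthetic haploid gene-trap screen with known ground truth.

The simulator emulates the experiment behind the screen pipeline: a random
genome with gene models, a genome-wide library of retroviral insertions (one
per haploid cell), genotype-dependent survival under drug selection, and
inverse-PCR sequencing reads whose genomic fragments terminate at MseI (TTAA)
or NlaIII (CATG) restriction sites.

Every operation derives its random stream from ``(stage, config.seed)`` so the
whole pipeline is bit-reproducible and stages are independent of call order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .annotation import classify_insertion, index_models
from .config import ScreenSimConfig
from .models import GeneModel, InsertionEvent

BASES = np.frombuffer(b"ACGT", dtype="S1")
RESTRICTION_MOTIFS = ("TTAA", "CATG")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Fixed per-stage offsets mixed into the seed sequence so each stage draws an
# independent stream regardless of how many values earlier stages consumed.
_STAGE = {"genome": 1, "insertions": 2, "selection": 3, "reads": 4}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _rng(stage: str, config: ScreenSimConfig) -> np.random.Generator:
    return np.random.default_rng([_STAGE[stage], config.seed])


@dataclass
class SyntheticGenome:
    """Per-chromosome sequences over {A,C,G,T}; no ambiguous bases."""

    sequences: dict[str, str]

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one sequenced (or skipped) insertion event."""

    cell_id: int
    chromosome: str
    position: int
    orientation: str
    n_reads: int
    skipped: bool


@dataclass
class ReadSet:
    """Synthesized FASTQ reads plus the truth table mapping reads to events."""

    reads: list[tuple[str, str]]  # (read_id, sequence)
    truth: list[TruthRecord] = field(default_factory=list)

    def truth_by_read(self) -> dict[str, TruthRecord]:
        out: dict[str, TruthRecord] = {}
        for rec in self.truth:
            if rec.skipped:
                continue
            for i in range(rec.n_reads):
                out[f"cell{rec.cell_id}:{i}"] = rec
        return out


def generate_genome(config: ScreenSimConfig) -> tuple[SyntheticGenome, list[GeneModel]]:
    """Generate an i.i.d.-uniform random genome and place gene models on it.

    Genes are placed left-to-right on successive chromosomes without overlap
    (unless ``allow_gene_overlap``), each spanning ``gene_span`` bp with a
    random exon count in ``exons_per_gene`` and introns of at least
    ``intron_min`` bp.  Raises ``ValueError`` if the genes do not fit.
    """
    rng = _rng("genome", config)
    sequences = {
        f"chr{i + 1}": rng.choice(BASES, size=config.chromosome_length)
        .tobytes()
        .decode("ascii")
        for i in range(config.n_chromosomes)
    }
    genome = SyntheticGenome(sequences)
    models = _place_genes(rng, genome, config)
    return genome, models


def _place_genes(
    rng: np.random.Generator, genome: SyntheticGenome, config: ScreenSimConfig
) -> list[GeneModel]:
    chroms = genome.chromosomes
    span = config.gene_span
    per_chrom = -(-config.n_genes // len(chroms))  # ceil
    models: list[GeneModel] = []
    gene_no = 0
    for chrom in chroms:
        if gene_no >= config.n_genes:
            break
        n_here = min(per_chrom, config.n_genes - gene_no)
        clen = genome.length(chrom)
        if config.allow_gene_overlap:
            starts = np.sort(rng.integers(0, clen - span, size=n_here))
        else:
            slack = clen - n_here * span
            if slack < 0:
                raise ValueError(
                    f"infeasible packing: {n_here} genes of span {span} bp "
                    f"do not fit on {chrom} ({clen} bp)"
                )
            # distribute the slack as random gaps between consecutive genes
            gaps = rng.multinomial(slack, np.ones(n_here + 1) / (n_here + 1))
            starts = np.cumsum(gaps[:-1]) + np.arange(n_here) * span
        for start in starts:
            gene_no += 1
            models.append(
                _make_gene(rng, f"gene{gene_no:04d}", chrom, int(start), config)
            )
    return models


def _make_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    start: int,
    config: ScreenSimConfig,
) -> GeneModel:
    lo, hi = config.exons_per_gene
    n_exons = int(rng.integers(lo, hi + 1))
    span = config.gene_span
    strand = "+" if rng.random() < 0.5 else "-"
    if n_exons == 1:
        return GeneModel(gene_id, chrom, strand, ((start, start + span),))
    # alternate exon/intron segments over the span: exons >= 1 bp,
    # introns >= intron_min; spread the remaining length randomly
    n_introns = n_exons - 1
    n_segments = 2 * n_exons - 1
    free = span - n_exons - n_introns * config.intron_min
    if free < 0:
        raise ValueError(
            f"gene_span {span} too small for {n_exons} exons with "
            f"introns >= {config.intron_min}"
        )
    extra = rng.multinomial(free, np.ones(n_segments) / n_segments)
    exons = []
    pos = start
    for i in range(n_segments):
        length = (1 if i % 2 == 0 else config.intron_min) + int(extra[i])
        if i % 2 == 0:
            exons.append((pos, pos + length))
        pos += length
    # absorb any rounding into the last exon so the span is exact
    last_start, _ = exons[-1]
    exons[-1] = (last_start, start + span)
    return GeneModel(gene_id, chrom, strand, tuple(exons))


def simulate_insertions(
    genome: SyntheticGenome, config: ScreenSimConfig
) -> list[InsertionEvent]:
    """Draw the insertion library: positions uniform over the genome,
    orientations an independent fair coin, one event per cell."""
    if config.n_insertions <= 0:
        raise ValueError("n_insertions must be positive")
    rng = _rng("insertions", config)
    chroms = genome.chromosomes
    lengths = np.array([genome.length(c) for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=config.n_insertions, p=lengths / lengths.sum())
    events: list[InsertionEvent] = []
    for cell_id, ci in enumerate(chrom_idx):
        chrom = chroms[ci]
        pos = int(rng.integers(0, genome.length(chrom)))
        orientation = "+" if rng.random() < 0.5 else "-"
        events.append(InsertionEvent(cell_id, chrom, pos, orientation))
    return events


def apply_selection(
    events: list[InsertionEvent],
    gene_models: list[GeneModel],
    config: ScreenSimConfig,
) -> list[InsertionEvent]:
    """Drug selection: a cell survives with probability ``p_survive_resistant``
    if its insertion inactivates any resistance gene, else
    ``p_survive_background``."""
    known = {m.gene_id for m in gene_models}
    unknown = config.resistance_genes - known
    if unknown:
        raise ValueError(f"unknown resistance gene id(s): {sorted(unknown)}")
    rng = _rng("selection", config)
    index = index_models(gene_models)
    survivors = []
    for event in events:
        hits = classify_insertion_event(event, index)
        resistant = any(
            gid in config.resistance_genes and inactivating for gid, inactivating in hits
        )
        p = config.p_survive_resistant if resistant else config.p_survive_background
        if rng.random() < p:
            survivors.append(event)
    return survivors


def classify_insertion_event(event: InsertionEvent, index) -> list[tuple[str, bool]]:
    """Classify a simulated event exactly as the analysis pipeline will
    classify the called site (same position/orientation conventions)."""
    return classify_insertion(
        event.chromosome, event.position, event.orientation, index, warn_missing=False
    )


def _truncate_at_motif(seq: str) -> str:
    """Inverse-PCR fragment rule: the genomic fragment ends at the first
    MseI/NlaIII site, so the read runs through the end of the leftmost motif."""
    best = None
    for motif in RESTRICTION_MOTIFS:
        i = seq.find(motif)
        if i >= 0 and (best is None or i < best[0]):
            best = (i, motif)
    if best is None:
        return seq
    i, motif = best
    return seq[: i + len(motif)]


def synthesize_reads(
    events: list[InsertionEvent],
    genome: SyntheticGenome,
    config: ScreenSimConfig,
) -> ReadSet:
    """Sequence the surviving pool.

    Per event, a read count is drawn from the shifted negative binomial depth
    model; each read is the genomic sequence starting at the insertion
    position, read in the proviral orientation (reverse complement for '-'),
    truncated at the end of the first TTAA/CATG within ``read_length``.
    Events too close to the chromosome end to yield >= 20 bases are recorded
    in the truth table with a skip flag.
    """
    if not events:
        raise ValueError("no surviving events to sequence")
    rng = _rng("reads", config)
    # depth_dispersion is the quadratic overdispersion alpha (Var = mu + alpha mu^2),
    # so the NB size is k = 1/alpha; numpy's negative_binomial(n, p) has
    # mean = n (1-p)/p  =>  p = k / (k + mean)
    mean, k = config.depth_mean - 1.0, 1.0 / config.depth_dispersion
    depths = 1 + rng.negative_binomial(k, k / (k + mean), size=len(events))
    reads: list[tuple[str, str]] = []
    truth: list[TruthRecord] = []
    for event, n_reads in zip(events, depths):
        seq = _event_sequence(event, genome, config.read_length)
        if seq is None or len(seq) < 20:
            warnings.warn(
                f"event cell{event.cell_id} at {event.chromosome}:{event.position} "
                "too close to chromosome end; skipped",
                stacklevel=2,
            )
            truth.append(
                TruthRecord(
                    event.cell_id, event.chromosome, event.position,
                    event.orientation, 0, skipped=True,
                )
            )
            continue
        seq = _truncate_at_motif(seq)
        n = int(n_reads)
        for i in range(n):
            reads.append((f"cell{event.cell_id}:{i}", config.ltr_prefix + seq))
        truth.append(
            TruthRecord(
                event.cell_id, event.chromosome, event.position,
                event.orientation, n, skipped=False,
            )
        )
    return ReadSet(reads=reads, truth=truth)


def _event_sequence(
    event: InsertionEvent, genome: SyntheticGenome, read_length: int
) -> str | None:
    """Genomic sequence read from the junction base in proviral direction."""
    chrom_seq = genome[event.chromosome]
    pos = event.position
    if event.orientation == "+":
        seq = chrom_seq[pos : pos + read_length]
    else:
        start = max(0, pos - read_length + 1)
        seq = revcomp(chrom_seq[start : pos + 1])
    return seq if seq else None
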