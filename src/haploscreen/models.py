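"""Core domain records for the gene-trap screen pipeline.

Coordinates are 0-based half-open everywhere inside the package; the 1-based
conventions of GTF and SAM are converted at the parser boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

Interval = tuple[int, int]

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GeneModel:
    """A gene: span, strand and ordered exon intervals.

    The gene span is [first exon start, last exon end); everything inside the
    span that is not exonic is intronic.  Exons must be sorted, disjoint and
    non-empty.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"gene {self.gene_id}: empty exon [{start},{end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons unsorted or overlapping")
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def is_exonic(self, position: int) -> bool:
        return any(s <= position < e for s, e in self.exons)

    def introns(self) -> Iterator[Interval]:
        for (_, left_end), (right_start, _) in zip(self.exons, self.exons[1:]):
            yield (left_end, right_start)


@dataclass(frozen=True)
class InsertionEvent:
    """One proviral integration in one (haploid) cell.

    ``position`` is the 0-based first genomic base 3' of the proviral LTR
    junction; ``orientation`` is the proviral transcriptional direction on the
    forward strand of the genome.
    """

    cell_id: int
    chromosome: str
    position: int
    orientation: str

    def __post_init__(self) -> None:
        if self.orientation not in STRANDS:
            raise ValueError(f"orientation must be + or -, got {self.orientation!r}")


@dataclass(frozen=True)
class AlignedSite:
    """A uniquely placed read: forward-strand junction coordinate + strand."""

    read_id: str
    chromosome: str
    position: int
    orientation: str


@dataclass(frozen=True)
class InsertionSite:
    """A deduplicated integration point with its supporting read count."""

    chromosome: str
    position: int
    orientation: str
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")


@dataclass(frozen=True)
class GeneCounts:
    """Unique inactivating insertion sites in a gene, and their summed reads."""

    gene_id: str
    n_inactivating_sites: int
    total_reads: int


@dataclass
class EnrichmentResult:
    """Per-gene Fisher's-exact enrichment row (one bubble of the bubble plot)."""

    gene_id: str
    k_selected: int
    n_selected_total: int
    k_control: int
    n_control_total: int
    p_value: float
    bubble_n: int = 0
    chrom_order_index: int = -1
    total_reads: int = 0
    bh_q: float = field(default=float("nan"))
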