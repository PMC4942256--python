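"""Simulator configuration for the synthetic haploid gene-trap screen."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ScreenSimConfig:
    """All knobs of the synthetic screen.

    Defaults describe a desk-scale stand-in for the real experiment: a
    retroviral gene-trap library in a haploid cell population (the real screen
    used ~75 million insertions and 50-bp single-end reads), drug selection in
    which only cells carrying an inactivating insertion in a resistance gene
    survive at an appreciable rate, and inverse-PCR sequencing whose fragments
    terminate at MseI (TTAA) or NlaIII (CATG) sites.

    Parameters
    ----------
    n_chromosomes, chromosome_length
        Synthetic genome shape.
    n_genes, exons_per_gene
        Number of gene models to place and the inclusive range of exon counts
        per gene.
    gene_span, intron_min
        Target gene span in bp and the minimum intron length (>= 50).
    n_insertions
        Library size (one integration per cell; haploid).
    resistance_genes
        Gene ids whose inactivation confers drug resistance.
    p_survive_resistant, p_survive_background
        Per-cell survival probabilities under selection for cells carrying /
        not carrying an inactivating insertion in a resistance gene.
    read_length
        Sequenced read length (bp); the platform in the emulated experiment
        produced 50-bp single-end reads.
    depth_mean, depth_dispersion
        Per-site read-count model: 1 + NegativeBinomial with mean
        ``depth_mean - 1`` and overdispersion ``depth_dispersion`` (the alpha
        of Var = mu + alpha mu^2; NB size = 1/alpha).  Support is >= 1, and
        the defaults leave ~1% of sites at a single read, so the singleton
        filter removes a nontrivial tail.
    ltr_prefix
        Optional fixed vector sequence prepended to every read, to exercise
        vector-trimming code paths.  Empty by default (vector trimming assumed
        done upstream).
    allow_gene_overlap, multi_integration
        Config flags; both off by default.
    seed
        Seed for every random draw; all operations are bit-reproducible for a
        fixed config.
    """

    n_chromosomes: int = 2
    chromosome_length: int = 100_000
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (3, 3)
    gene_span: int = 3_000
    intron_min: int = 50
    n_insertions: int = 1_000
    resistance_genes: frozenset[str] = field(default_factory=frozenset)
    p_survive_resistant: float = 0.9
    p_survive_background: float = 0.001
    read_length: int = 50
    depth_mean: float = 20.0
    depth_dispersion: float = 0.5
    ltr_prefix: str = ""
    allow_gene_overlap: bool = False
    multi_integration: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_survive_resistant", "p_survive_background"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if self.intron_min < 50:
            raise ValueError("intron_min must be >= 50")
        lo, hi = self.exons_per_gene
        if not 1 <= lo <= hi:
            raise ValueError("exons_per_gene must be an increasing range >= 1")
        if self.n_genes * self.gene_span > self.n_chromosomes * self.chromosome_length:
            raise ValueError(
                "infeasible packing: n_genes * gene_span exceeds total genome length"
            )
        if self.depth_mean <= 1.0:
            raise ValueError("depth_mean must exceed 1 (support of counts is >= 1)")
        self.resistance_genes = frozenset(self.resistance_genes)
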