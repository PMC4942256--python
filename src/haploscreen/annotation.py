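"""Exon/intron classification of insertion sites and per-gene count tables.

An insertion is counted as gene-inactivating if it lands in an exon (any
orientation) or in an intron with the provirus in the gene's transcriptional
(sense) orientation; antisense intronic insertions are tolerated.  Overlapping
genes are evaluated independently.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass

from .models import GeneCounts, GeneModel, InsertionSite


@dataclass
class ModelIndex:
    """Gene models bucketed per chromosome, sorted by span start."""

    by_chrom: dict[str, list[GeneModel]]
    starts: dict[str, list[int]]
    gene_ids: list[str]

    def overlapping(self, chrom: str, position: int) -> list[GeneModel]:
        models = self.by_chrom.get(chrom)
        if models is None:
            return []
        # genes are few and spans short; scan the candidates left of position
        hi = bisect_right(self.starts[chrom], position)
        return [m for m in models[:hi] if position < m.end]


def index_models(models: list[GeneModel]) -> ModelIndex:
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chromosome, []).append(m)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda m: (m.start, m.gene_id))
    starts = {c: [m.start for m in ms] for c, ms in by_chrom.items()}
    return ModelIndex(by_chrom, starts, [m.gene_id for m in models])


def classify_insertion(
    chromosome: str,
    position: int,
    orientation: str,
    index: ModelIndex,
    *,
    exon_requires_sense: bool = False,
    warn_missing: bool = True,
) -> list[tuple[str, bool]]:
    """Classify one insertion against every gene whose span contains it.

    Returns ``[(gene_id, inactivating), ...]``; empty for intergenic sites.
    Exonic hits inactivate regardless of orientation (unless
    ``exon_requires_sense``); intronic hits inactivate only in the sense
    orientation.  A chromosome absent from the annotation yields an empty
    list with a warning.
    """
    if chromosome not in index.by_chrom:
        if warn_missing:
            warnings.warn(
                f"chromosome {chromosome!r} absent from annotation", stacklevel=2
            )
        return []
    out: list[tuple[str, bool]] = []
    for model in index.overlapping(chromosome, position):
        sense = orientation == model.strand
        if model.is_exonic(position):
            inactivating = sense if exon_requires_sense else True
        else:
            inactivating = sense
        out.append((model.gene_id, inactivating))
    return out


def classify_site(
    site: InsertionSite, index: ModelIndex, **kwargs
) -> list[tuple[str, bool]]:
    return classify_insertion(
        site.chromosome, site.position, site.orientation, index, **kwargs
    )


def per_gene_counts(
    sites: list[InsertionSite],
    models: list[GeneModel],
    *,
    exon_requires_sense: bool = False,
) -> list[GeneCounts]:
    """Count unique inactivating sites (and their summed reads) per gene.

    Every gene in the annotation gets a row, zero-count genes included.  A
    site inside two overlapping genes is counted once for each.
    """
    index = index_models(models)
    n_sites = {m.gene_id: 0 for m in models}
    n_reads = {m.gene_id: 0 for m in models}
    for site in sites:
        for gene_id, inactivating in classify_site(
            site, index, exon_requires_sense=exon_requires_sense, warn_missing=False
        ):
            if inactivating:
                n_sites[gene_id] += 1
                n_reads[gene_id] += site.read_count
    return [GeneCounts(m.gene_id, n_sites[m.gene_id], n_reads[m.gene_id]) for m in models]
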