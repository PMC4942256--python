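"""End-to-end screen drivers: simulate -> map -> call -> count -> enrich.

Two entry points: ``run_screen`` runs the full read-level pipeline on a
synthetic screen (what the sequencing experiment plus analysis would do),
and ``run_counts_screen`` short-circuits sequencing to work at the
insertion-site level (useful for statistical calibration at many replicates).
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation import per_gene_counts
from .config import ScreenSimConfig
from .enrichment import EnrichmentResult, screen_enrichment
from .mapping import map_reads
from .models import AlignedSite, GeneCounts, GeneModel, InsertionSite
from .simulate import (
    ReadSet,
    SyntheticGenome,
    apply_selection,
    generate_genome,
    simulate_insertions,
    synthesize_reads,
)
from .sites import call_sites, collapse_sites, filter_proximal


@dataclass
class ScreenRun:
    """Everything produced by one simulated screen."""

    genome: SyntheticGenome
    models: list[GeneModel]
    reads: ReadSet
    sites: list[InsertionSite]
    selected_counts: list[GeneCounts]
    control_counts: list[GeneCounts]
    results: list[EnrichmentResult]


def control_library_counts(
    events, models: list[GeneModel]
) -> list[GeneCounts]:
    """Per-gene counts for the unselected library (the control pool).

    The control library is the site catalogue of mutagenized cells before
    selection; each event contributes one unique site with one nominal read
    (read depth of the control pool does not enter the site-count statistic).
    """
    # deduplicate coincident events (possible at high library density)
    sites = collapse_sites(
        [AlignedSite(f"cell{e.cell_id}", e.chromosome, e.position, e.orientation)
         for e in events]
    )
    return per_gene_counts(sites, models)


def run_screen(config: ScreenSimConfig, *, min_length: int = 20) -> ScreenRun:
    """Full pipeline: synthetic screen through Fisher enrichment."""
    genome, models = generate_genome(config)
    library = simulate_insertions(genome, config)
    survivors = apply_selection(library, models, config)
    reads = synthesize_reads(survivors, genome, config)
    aligned = map_reads(reads.reads, genome, min_length, vector_prefix=config.ltr_prefix)
    sites = call_sites(aligned)
    selected_counts = per_gene_counts(sites, models)
    control_counts = control_library_counts(library, models)
    results = screen_enrichment(selected_counts, control_counts, models)
    return ScreenRun(
        genome, models, reads, sites, selected_counts, control_counts, results
    )


def run_counts_screen(config: ScreenSimConfig) -> list[EnrichmentResult]:
    """Site-level pipeline without read synthesis or mapping.

    Survivors are counted directly as insertion sites (one read each, the
    singleton filter is not applied since depth is not simulated); useful for
    null-calibration sweeps where sequencing adds cost but no signal.
    """
    genome, models = generate_genome(config)
    library = simulate_insertions(genome, config)
    survivors = apply_selection(library, models, config)
    sel_sites = [
        InsertionSite(e.chromosome, e.position, e.orientation, 1) for e in survivors
    ]
    sel_sites = filter_proximal(sorted(
        sel_sites, key=lambda s: (s.chromosome, s.position, s.orientation)
    ))
    selected_counts = per_gene_counts(sel_sites, models)
    control_counts = control_library_counts(library, models)
    return screen_enrichment(selected_counts, control_counts, models)
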