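"""Per-gene Fisher's-exact enrichment of inactivating insertions.

For every annotated gene, the number of unique inactivating insertion sites
in the selected (drug-resistant) pool is compared against the number in a
control library of mutagenized, unselected cells; the one-sided Fisher's
exact test on the 2x2 table

    [[k_sel, n_sel - k_sel],
     [k_ctrl, n_ctrl - k_ctrl]]

gives the enrichment p-value, where n_sel and n_ctrl are the genome-wide
totals of inactivating sites in each pool.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .models import EnrichmentResult, GeneCounts, GeneModel


def fisher_enrichment(
    k_sel: int, n_sel: int, k_ctrl: int, n_ctrl: int, *, two_sided: bool = False
) -> float:
    """One-sided (enrichment-in-selected) Fisher's exact p-value.

    Equals the hypergeometric upper-tail sum P(X >= k_sel) with population
    n_sel + n_ctrl, k_sel + k_ctrl successes and n_sel draws.  ``two_sided``
    switches to the standard two-sided test.
    """
    for name, v in (("k_sel", k_sel), ("n_sel", n_sel), ("k_ctrl", k_ctrl), ("n_ctrl", n_ctrl)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if k_sel > n_sel or k_ctrl > n_ctrl:
        raise ValueError("k must not exceed n")
    if n_sel == 0 or n_ctrl == 0:
        raise ValueError("pool totals must be positive")
    if two_sided:
        table = [[k_sel, n_sel - k_sel], [k_ctrl, n_ctrl - k_ctrl]]
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    # one-sided Fisher == hypergeometric upper tail P(X >= k_sel)
    return float(
        stats.hypergeom.sf(k_sel - 1, n_sel + n_ctrl, k_sel + k_ctrl, n_sel)
    )


def screen_enrichment(
    selected: list[GeneCounts],
    control: list[GeneCounts],
    models: list[GeneModel] | None = None,
    *,
    two_sided: bool = False,
) -> list[EnrichmentResult]:
    """Fisher enrichment for every gene, selected pool vs control library.

    Both count tables must cover the same genes.  Results carry the
    chromosomal order index (bubble-plot x-axis) when gene models are given,
    the unique-site count as the bubble size, and a Benjamini-Hochberg q-value
    column appended for convenience (not part of the original analysis, which
    reported raw p-values).
    """
    sel_genes = [g.gene_id for g in selected]
    ctrl_genes = [g.gene_id for g in control]
    if set(sel_genes) != set(ctrl_genes):
        diff = set(sel_genes) ^ set(ctrl_genes)
        raise ValueError(f"gene sets differ between pools: {sorted(diff)[:10]}")
    ctrl_by_gene = {g.gene_id: g for g in control}
    n_sel = sum(g.n_inactivating_sites for g in selected)
    n_ctrl = sum(g.n_inactivating_sites for g in control)
    order = _chromosomal_order(sel_genes, models)
    results = []
    for g in selected:
        c = ctrl_by_gene[g.gene_id]
        p = fisher_enrichment(
            g.n_inactivating_sites, n_sel, c.n_inactivating_sites, n_ctrl,
            two_sided=two_sided,
        )
        results.append(
            EnrichmentResult(
                gene_id=g.gene_id,
                k_selected=g.n_inactivating_sites,
                n_selected_total=n_sel,
                k_control=c.n_inactivating_sites,
                n_control_total=n_ctrl,
                p_value=p,
                bubble_n=g.n_inactivating_sites,
                chrom_order_index=order[g.gene_id],
                total_reads=g.total_reads,
            )
        )
    qs = stats.false_discovery_control([r.p_value for r in results], method="bh")
    for r, q in zip(results, qs):
        r.bh_q = float(q)
    results.sort(key=lambda r: r.chrom_order_index)
    return results


def _chromosomal_order(
    gene_ids: list[str], models: list[GeneModel] | None
) -> dict[str, int]:
    if models is None:
        ranked = sorted(gene_ids)
    else:
        pos = {m.gene_id: (m.chromosome, m.start, m.gene_id) for m in models}
        ranked = sorted(gene_ids, key=lambda g: pos.get(g, ("", 0, g)))
    return {g: i for i, g in enumerate(ranked)}


def rank_genes(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Rank by ascending p-value; ties broken by gene id for reproducibility."""
    return sorted(results, key=lambda r: (r.p_value, r.gene_id))


def display_filter(
    results: list[EnrichmentResult], min_total_reads: int = 10
) -> list[EnrichmentResult]:
    """Drop genes with fewer than ``min_total_reads`` selected-pool reads.

    The default threshold of 10 matches the primary bubble plots; 50 was
    used for the validation screens.  "Less than" excludes only values
    strictly below the threshold.
    """
    return [r for r in results if r.total_reads >= min_total_reads]


def validate_source_counts(
    table, gene_id: str, expected_sites: int
) -> bool:
    """Check a published per-gene site table against an expected count.

    ``table`` is a mapping or DataFrame-like with gene ids and unique
    inactivating site counts; intended for reconciling against supplementary
    source-data files when they are available locally.
    """
    if hasattr(table, "set_index"):
        counts = dict(zip(table.iloc[:, 0], table.iloc[:, 1]))
    else:
        counts = dict(table)
    return int(counts.get(gene_id, -1)) == int(expected_sites)


def to_frame(results: list[EnrichmentResult]):
    """Tidy DataFrame view of enrichment results (bubble-plot data)."""
    import pandas as pd

    rows = [
        {
            "gene_id": r.gene_id,
            "chrom_order_index": r.chrom_order_index,
            "k_selected": r.k_selected,
            "k_control": r.k_control,
            "total_reads": r.total_reads,
            "p_value": r.p_value,
            "bh_q": r.bh_q,
            "bubble_n": r.bubble_n,
            "neg_log10_p": -np.log10(r.p_value) if r.p_value > 0 else np.inf,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
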