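"""Collapse aligned reads into unique insertion sites and filter them.

Two site-level filters follow the original analysis: sites separated by only
1 or 2 bp are discarded (alignment jitter of a single junction), and sites
supported by a single sequencing read are discarded.
"""

from __future__ import annotations

from collections import Counter

from .models import AlignedSite, InsertionSite


def collapse_sites(aligned: list[AlignedSite]) -> list[InsertionSite]:
    """One site per distinct (chromosome, position, orientation), carrying the
    number of contributing reads; sorted by chromosome then position."""
    counts = Counter((a.chromosome, a.position, a.orientation) for a in aligned)
    return [
        InsertionSite(chrom, pos, orientation, n)
        for (chrom, pos, orientation), n in sorted(counts.items())
    ]


def filter_proximal(
    sites: list[InsertionSite], *, keep_max_reads: bool = False
) -> list[InsertionSite]:
    """Discard sites with a neighbour at 1-2 bp on the same chromosome.

    Proximity is orientation-blind: a 1-2 bp shift is jitter of one junction
    regardless of the reported strand.  Removal is symmetric — every member of
    a proximal cluster goes.  With ``keep_max_reads`` the highest-count member
    of each cluster is retained instead (ties broken by position).
    """
    by_chrom: dict[str, list[InsertionSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chromosome, []).append(s)
    kept: list[InsertionSite] = []
    for chrom_sites in by_chrom.values():
        chrom_sites.sort(key=lambda s: (s.position, s.orientation))
        n = len(chrom_sites)
        proximal = [False] * n
        for i in range(n - 1):
            j = i + 1
            while j < n and chrom_sites[j].position - chrom_sites[i].position <= 2:
                if 1 <= chrom_sites[j].position - chrom_sites[i].position <= 2:
                    proximal[i] = proximal[j] = True
                j += 1
        if keep_max_reads:
            # connected clusters under the <=2 bp adjacency; keep one per cluster
            cluster: list[int] = []
            clusters: list[list[int]] = []
            for i in range(n):
                if not proximal[i]:
                    continue
                if cluster and chrom_sites[i].position - chrom_sites[cluster[-1]].position > 2:
                    clusters.append(cluster)
                    cluster = []
                cluster.append(i)
            if cluster:
                clusters.append(cluster)
            winners = {
                max(c, key=lambda i: (chrom_sites[i].read_count, -chrom_sites[i].position))
                for c in clusters
            }
            kept.extend(
                s for i, s in enumerate(chrom_sites) if not proximal[i] or i in winners
            )
        else:
            kept.extend(s for i, s in enumerate(chrom_sites) if not proximal[i])
    return sorted(kept, key=lambda s: (s.chromosome, s.position, s.orientation))


def filter_singletons(sites: list[InsertionSite]) -> list[InsertionSite]:
    """Discard sites represented by only one sequencing read."""
    return [s for s in sites if s.read_count > 1]


def call_sites(
    aligned: list[AlignedSite], *, keep_max_reads: bool = False
) -> list[InsertionSite]:
    """Collapse then filter, in the order of the original analysis:
    proximity filter first, singleton filter second."""
    sites = collapse_sites(aligned)
    sites = filter_proximal(sites, keep_max_reads=keep_max_reads)
    return filter_singletons(sites)
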