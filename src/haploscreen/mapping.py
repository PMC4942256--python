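"""Read trimming and unique exact-match mapping.

The mapping rule mirrors the original analysis: no mismatches, and a read is
kept only if it has a single alignment site over both strands; everything
else is discarded.  Reads are first trimmed after the first restriction site
(TTAA for MseI, CATG for NlaIII) so that fragments shorter than the read
length can still be placed.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pysam

from .models import AlignedSite
from .simulate import RESTRICTION_MOTIFS, SyntheticGenome, revcomp

DEFAULT_MIN_LENGTH = 20


def trim_at_restriction_site(sequence: str) -> str:
    """Return the prefix of ``sequence`` ending at the last base of the
    leftmost TTAA/CATG occurrence; the sequence unchanged if neither occurs.

    The restriction site itself is retained.  Idempotent: the trimmed read
    still ends in the motif, and no earlier occurrence can exist in a prefix.
    """
    if not sequence:
        raise ValueError("empty read")
    best: tuple[int, str] | None = None
    for motif in RESTRICTION_MOTIFS:
        i = sequence.find(motif)
        if i >= 0 and (best is None or i < best[0]):
            best = (i, motif)
    if best is None:
        return sequence
    i, motif = best
    return sequence[: i + len(motif)]


def strip_vector_prefix(sequence: str, vector_prefix: str) -> str:
    """Remove a known vector (LTR) prefix by literal match, if present."""
    if vector_prefix and sequence.startswith(vector_prefix):
        return sequence[len(vector_prefix) :]
    return sequence


def _occurrences(haystack: str, needle: str, limit: int) -> list[int]:
    """Start indices of ``needle`` in ``haystack``, stopping after ``limit``."""
    out: list[int] = []
    i = haystack.find(needle)
    while i >= 0 and len(out) < limit:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def map_reads(
    reads: Iterable[tuple[str, str]],
    genome: SyntheticGenome | Mapping[str, str],
    min_length: int = DEFAULT_MIN_LENGTH,
    *,
    vector_prefix: str = "",
) -> list[AlignedSite]:
    """Place trimmed reads on the genome; keep unique full-length exact matches.

    A read is retained iff, after optional vector-prefix removal and
    restriction-site trimming, it is at least ``min_length`` bp and matches
    the genome exactly once over both strands.  The reported position is the
    forward-strand coordinate of the read's first sequenced base (for a
    reverse-strand match, the last base of the matched interval), i.e. the
    LTR-junction base, so both orientations report the same site convention.
    """
    chrom_seqs = (
        genome.sequences if isinstance(genome, SyntheticGenome) else dict(genome)
    )
    # identical sequences place identically: resolve each distinct sequence once
    placements: dict[str, tuple[str, int, str] | None] = {}
    out: list[AlignedSite] = []
    for read_id, raw in reads:
        seq = strip_vector_prefix(raw, vector_prefix)
        seq = trim_at_restriction_site(seq)
        if len(seq) < min_length:
            continue
        if seq not in placements:
            placements[seq] = _place_unique(seq, chrom_seqs)
        placement = placements[seq]
        if placement is None:
            continue
        chrom, pos, orientation = placement
        out.append(AlignedSite(read_id, chrom, pos, orientation))
    return out


def _place_unique(
    seq: str, chrom_seqs: Mapping[str, str]
) -> tuple[str, int, str] | None:
    rc = revcomp(seq)
    hits: list[tuple[str, int, str]] = []
    for chrom, chrom_seq in chrom_seqs.items():
        for start in _occurrences(chrom_seq, seq, limit=2):
            hits.append((chrom, start, "+"))
            if len(hits) > 1:
                return None
        if rc != seq:
            for start in _occurrences(chrom_seq, rc, limit=2):
                hits.append((chrom, start + len(seq) - 1, "-"))
                if len(hits) > 1:
                    return None
        else:
            # palindromic read: the two strands give the same placement twice
            pass
    if len(hits) != 1:
        return None
    return hits[0]


def import_external_alignments(path: str) -> list[AlignedSite]:
    """Import unique alignments from a coordinate-sorted SAM/BAM file.

    Secondary, supplementary, unmapped and MAPQ-0 records are dropped.
    Positions follow the SAM convention converted to 0-based: the leftmost
    aligned base, with orientation '-' for reverse-strand records.
    """
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        header = fh.header.to_dict()
        if not header.get("SQ"):
            raise ValueError(f"{path}: missing SAM header / @SQ lines")
        if header.get("HD", {}).get("SO") != "coordinate":
            raise ValueError(f"{path}: alignments must be coordinate-sorted")
        out: list[AlignedSite] = []
        for rec in fh:
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or rec.mapping_quality == 0
            ):
                continue
            out.append(
                AlignedSite(
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_start,
                    "-" if rec.is_reverse else "+",
                )
            )
    return out
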