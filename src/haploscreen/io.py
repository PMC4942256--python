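"""Readers and writers for the package's on-disk formats.

Genome: FASTA.  Gene models: a GTF subset (``gene`` and ``exon`` features
with a ``gene_id`` attribute) or BED12.  Reads: FASTQ (Phred 33, constant
quality).  Sites, counts and truth tables: TSV.  GTF is 1-based closed and
BED/internal coordinates are 0-based half-open; conversion happens here and
only here.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import AlignedSite, GeneCounts, GeneModel, InsertionSite
from .simulate import ReadSet, SyntheticGenome, TruthRecord


# ---------------------------------------------------------------- FASTA

def write_fasta(genome: SyntheticGenome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in genome.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> SyntheticGenome:
    return SyntheticGenome(
        {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    )


# ---------------------------------------------------------------- FASTQ

def write_fastq(reads: ReadSet | list[tuple[str, str]], path: str | Path) -> None:
    pairs = reads.reads if isinstance(reads, ReadSet) else reads
    with open(path, "w") as fh:
        for read_id, seq in pairs:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")
    ]


# ---------------------------------------------------------------- GTF / BED12

def write_gtf(models: list[GeneModel], path: str | Path) -> None:
    """GTF subset: one ``gene`` and per-exon ``exon`` lines, 1-based closed."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}";'
            fh.write(
                f"{m.chromosome}\thaploscreen\tgene\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.chromosome}\thaploscreen\texon\t{s + 1}\t{e}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str | Path) -> list[GeneModel]:
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _, feature, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            gene_id = _gtf_gene_id(attrs)
            if feature == "exon":
                exons.setdefault(gene_id, []).append((int(start) - 1, int(end)))
                meta.setdefault(gene_id, (chrom, strand))
            elif feature == "gene":
                meta.setdefault(gene_id, (chrom, strand))
    models = []
    for gene_id, (chrom, strand) in meta.items():
        if gene_id not in exons:
            raise ValueError(f"gene {gene_id} has no exon records")
        models.append(GeneModel(gene_id, chrom, strand, tuple(sorted(exons[gene_id]))))
    models.sort(key=lambda m: (m.chromosome, m.start, m.gene_id))
    return models


def _gtf_gene_id(attrs: str) -> str:
    for field in attrs.split(";"):
        field = field.strip()
        if field.startswith("gene_id"):
            return field.split(None, 1)[1].strip('"')
    raise ValueError(f"no gene_id attribute in {attrs!r}")


def write_bed12(models: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            sizes = ",".join(str(e - s) for s, e in m.exons) + ","
            starts = ",".join(str(s - m.start) for s, _ in m.exons) + ","
            fh.write(
                f"{m.chromosome}\t{m.start}\t{m.end}\t{m.gene_id}\t0\t{m.strand}\t"
                f"{m.start}\t{m.end}\t0\t{len(m.exons)}\t{sizes}\t{starts}\n"
            )


def read_bed12(path: str | Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (start + off, start + off + size) for off, size in zip(offsets, sizes)
            )
            models.append(GeneModel(name, chrom, strand, exons))
    models.sort(key=lambda m: (m.chromosome, m.start, m.gene_id))
    return models


# ---------------------------------------------------------------- TSV tables

def write_truth_table(truth: list[TruthRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "cell_id": t.cell_id,
                "chrom": t.chromosome,
                "pos": t.position,
                "orientation": t.orientation,
                "n_reads": t.n_reads,
                "skip_flag": int(t.skipped),
            }
            for t in truth
        ]
    ).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        TruthRecord(
            int(r.cell_id), str(r.chrom), int(r.pos), str(r.orientation),
            int(r.n_reads), bool(r.skip_flag),
        )
        for r in df.itertuples()
    ]


def write_aligned_sites(aligned: list[AlignedSite], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"read_id": a.read_id, "chrom": a.chromosome, "pos0": a.position,
             "orientation": a.orientation}
            for a in aligned
        ]
    ).to_csv(path, sep="\t", index=False)


def read_aligned_sites(path: str | Path) -> list[AlignedSite]:
    df = pd.read_csv(path, sep="\t")
    return [
        AlignedSite(str(r.read_id), str(r.chrom), int(r.pos0), str(r.orientation))
        for r in df.itertuples()
    ]


def write_sites(sites: list[InsertionSite], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"chrom": s.chromosome, "pos0": s.position, "orientation": s.orientation,
             "read_count": s.read_count}
            for s in sites
        ]
    ).to_csv(path, sep="\t", index=False)


def read_sites(path: str | Path) -> list[InsertionSite]:
    df = pd.read_csv(path, sep="\t")
    return [
        InsertionSite(str(r.chrom), int(r.pos0), str(r.orientation), int(r.read_count))
        for r in df.itertuples()
    ]


def write_gene_counts(counts: list[GeneCounts], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"gene_id": c.gene_id, "n_inactivating_sites": c.n_inactivating_sites,
             "total_reads": c.total_reads}
            for c in counts
        ]
    ).to_csv(path, sep="\t", index=False)


def read_gene_counts(path: str | Path) -> list[GeneCounts]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneCounts(str(r.gene_id), int(r.n_inactivating_sites), int(r.total_reads))
        for r in df.itertuples()
    ]
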