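"""Simulate a planted haploid gene-trap screen and write its artifacts.

A 2 x 1 Mb synthetic genome carries 100 genes; three of them confer drug
resistance when inactivated.  A library of 50,000 single-integration cells
is put through selection (survival 0.9 for resistant genotypes, 0.001
background) and the surviving pool is sequenced as 50-bp inverse-PCR reads.
Outputs: genome FASTA, GTF/BED12 annotation, FASTQ reads, truth table.
"""

from pathlib import Path

import haploscreen as hs
from haploscreen import io

OUT = Path(__file__).resolve().parent.parent / "scratch" / "screen"
PLANTED = frozenset({"gene0010", "gene0050", "gene0090"})


def main(seed: int = 1) -> None:
    cfg = hs.ScreenSimConfig(
        seed=seed,
        n_chromosomes=2,
        chromosome_length=1_000_000,
        n_genes=100,
        n_insertions=50_000,
        resistance_genes=PLANTED,
        p_survive_resistant=0.9,
        p_survive_background=0.001,
    )
    OUT.mkdir(parents=True, exist_ok=True)
    genome, models = hs.generate_genome(cfg)
    library = hs.simulate_insertions(genome, cfg)
    survivors = hs.apply_selection(library, models, cfg)
    reads = hs.synthesize_reads(survivors, genome, cfg)

    io.write_fasta(genome, OUT / "genome.fa")
    io.write_gtf(models, OUT / "genes.gtf")
    io.write_bed12(models, OUT / "genes.bed")
    io.write_fastq(reads, OUT / "reads.fastq")
    io.write_truth_table(reads.truth, OUT / "truth.tsv")
    io.write_gene_counts(
        hs.pipeline.control_library_counts(library, models), OUT / "control_counts.tsv"
    )

    n_skip = sum(t.skipped for t in reads.truth)
    print(f"library: {len(library)} insertions; survivors after selection: {len(survivors)}")
    print(f"reads: {len(reads.reads)} from {len(reads.truth) - n_skip} events "
          f"({n_skip} skipped near chromosome ends)")
    print(f"wrote genome, annotation, reads, truth and control counts -> {OUT}")


if __name__ == "__main__":
    main()
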