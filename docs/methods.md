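# Methods

## The screen model

`haploscreen` analyses loss-of-function screens performed by retroviral
gene-trap mutagenesis in a near-haploid human cell line. Because the cells
are haploid, a single integration that disrupts a gene produces a
loss-of-function phenotype. A mutagenized library is treated with a toxic
compound; clones whose disrupted gene confers resistance expand, and the
integration sites of the surviving pool are read out by inverse PCR:
genomic DNA is digested with MseI (cuts at TTAA) or NlaIII (CATG),
self-ligated, and the provirus–genome junctions amplified and sequenced as
50-bp single-end reads.

The analysis chain is:

1. **Trimming** — a read containing TTAA or CATG is cut *after* the leftmost
   restriction site (the genomic fragment physically ends there); the motif
   is retained in the read. Trimming is a prefix operation and idempotent.
2. **Mapping** — exact matching with no mismatches; a read is kept only if
   it has a single alignment site over both genome strands, and only if its
   trimmed length is at least `min_length` (default 20 bp; no floor is
   inherent to the protocol, 20 bp gives unique placement with high
   probability on the synthetic genomes used here).
3. **Site calling** — reads collapse to unique (chromosome, position,
   orientation) sites with read counts. Sites separated by only 1 or 2 bp
   are discarded (orientation-blind; 1–2 bp shifts are junction jitter);
   removal is symmetric over the whole proximal cluster, with an optional
   `keep_max_reads` mode that retains the best-supported member for
   sensitivity analysis. Sites supported by a single read are then
   discarded. Filter order is proximity first, then singletons; the order
   can matter (a singleton neighbouring a real site drags it down in the
   default order) and both orders are exercised in the tests.
4. **Classification** — an insertion inactivates a gene if it falls in an
   exon (any orientation) or in an intron with the provirus in the gene's
   transcriptional orientation; antisense intronic insertions are tolerated.
   Coordinates are 0-based half-open throughout; a site at an exon boundary
   belongs to the exon; overlapping genes are evaluated independently; UTR
   exons count as exons. An `exon_requires_sense` switch exists but is off
   by default.
5. **Enrichment** — for each annotated gene, a one-sided Fisher's exact test
   on `[[k_sel, n_sel−k_sel], [k_ctrl, n_ctrl−k_ctrl]]`, where `k` is the
   gene's unique inactivating site count and `n` the genome-wide total of
   inactivating sites in each pool (selected pool vs the pre-selection
   control library). The p-value is computed as the hypergeometric
   upper-tail sum, which is identical to the one-sided Fisher test; a
   two-sided option exists behind a flag. No multiple-testing correction is
   applied to the primary statistic; a Benjamini–Hochberg q-value column is
   appended for convenience and clearly not part of the original statistic.
   Genes with fewer than 10 selected-pool reads (50 in the validation-screen
   preset) are dropped from display output only; "less than" excludes only
   values strictly below the threshold.

### Coordinate and strand conventions

An insertion position is the 0-based first genomic base 3′ of the proviral
LTR junction. A plus-orientation read starts at that base and runs
rightward; a minus-orientation read runs leftward and is sequenced as the
reverse complement. The mapper therefore reports, for a reverse-strand
match, the forward-strand coordinate of the *last* base of the matched
interval — the junction base — so both orientations name the same site
convention and the pipeline recovers simulated junction coordinates
exactly. `import_external_alignments` (the escape hatch for externally
aligned data) instead follows the plain SAM convention, reporting the
leftmost aligned base for reverse-strand records; anyone comparing imported
hg19-scale alignments with internally mapped data should be aware the two
conventions differ by read-length−1 on the minus strand.

## The synthetic screen

The simulator is the package's ground-truth instrument, not a fixture. Its
stated world, scaled from the real experiment (~75 million insertions,
50-bp reads) to desk size:

| parameter | default | why |
|---|---|---|
| genome | 2 × 100 kb (acceptance runs use 2 × 1 Mb), i.i.d. uniform bases | repeat-free at read scale, so exact mapping is near-lossless |
| genes | 20 (100 at acceptance scale), span 3 kb, 3 exons, introns ≥ 50 bp | gives exonic and intronic territory in every gene |
| library | uniform positions, fair-coin orientation, one integration per haploid cell | clonal gene-trap lines; multi-integration is a flag, off |
| selection | survival 0.9 if an insertion inactivates a resistance gene, 0.001 otherwise | strong-selection regime of a drug screen |
| depth | 1 + NB(mean 19, α = 0.5), i.e. mean 20, Var = μ + αμ² | support ≥ 1; ~0.9% of sites draw a single read, so the singleton filter removes a real but small tail |
| reads | 50 bp, truncated through the first TTAA/CATG, Phred quality constant "I" | inverse-PCR fragment structure; no sequencing-error model |

`depth_dispersion` is the quadratic overdispersion coefficient α (the
convention of count-model genomics), not the NB size parameter; the size is
1/α = 2 at default. The read-count distribution of the real protocol is
unknown; this is a stand-in chosen once.

Events whose junction lies too close to a chromosome end to yield 20 bases
are recorded in the truth table with a skip flag rather than dropped. Reads
are written without any vector remnant by default (vector trimming is
assumed done); a configurable LTR prefix can be prepended to exercise the
literal-prefix vector-trimming path.

What the simulator does *not* emulate — and what a green test therefore does
not establish: sequencing errors and PCR chimeras (the exact-match mapper
would only discard more), clone expansion dynamics beyond a per-event
survival probability, non-uniform integration preferences of real
retroviruses, and genome repeat structure (a repeat-injection option exists
specifically to test multi-mapper discarding). Observability is limited by
design: an event whose fragment's restriction site lies within ~16 bp of the
junction yields only sub-20-bp reads (~12% of events under these motif
densities) and is invisible to any aligner under the trimming rule; an
event that draws one read is removed by the singleton filter. Recovery
claims are therefore stated over observable events.

## Adduct mass arithmetic

Ophiobolin A (C25H36O4) carries a 1,4-dicarbonyl that condenses with
primary amines — free ethanolamine (C2H7NO) or the head group of
phosphatidylethanolamine — in a Paal-Knorr reaction to a pyrrole, losing
two waters:

    m(adduct) = m(parent) + m(amine) − 2·m(H₂O)
    m/z([M+zH]^z+) = (m + z·1.007276) / z

Monoisotopic masses are computed from hard-coded IUPAC most-abundant-isotope
masses (C, H, N, O, P, S; ≥ 8 decimals); water is derived from the element
table rather than stored, so mass bookkeeping identities hold to 1e-9 Da.
The EIC window rounds the center m/z to 4 decimals first, then applies
±ppm (default 5) and rounds each bound half-up at 4 decimals — this
round-center-first convention reproduces the published window for the
protonated ethanolamine adduct (426.2982–426.3024) exactly; the original
instrument software's window convention is unknown, only the printed bounds
are authoritative. The parser accepts Hill-notation formulas; the parent
formula for ophiobolin A comes from standard chemical references, and the
mass — not the formula — is the anchored quantity. No isotope patterns,
fragmentation or retention modelling.

## Assay quantifications

* `pe_fraction`: Pi(PE) / (Pi(PE) + Pi(other)) from phosphorus analysis of
  TLC spots; scale-invariant, in [0, 1].
* `c14_flux` / `relative_flux`: scintillation counts per nmol total
  phospholipid phosphate, optionally relative to vehicle (vehicle ≡ 1).
* `leakage_percent`: 100·(F − F_vehicle)/(F_triton − F_vehicle) per time
  point, after per-condition background subtraction upstream. Values
  outside [0, 100] are reported unclipped with a flag — references are
  noisy measurements, not bounds.
* `relative_viability`: luminescence over the vehicle-treated signal.
* `ddct_relative_expression`: ΔCT = CT_target − CT_reference per sample,
  ΔΔCT = ΔCT_test − ΔCT_calibrator per primer pair, averaged over pairs;
  fold = 2^−ΔΔCT. Internally the sign convention is the standard one (an
  increase gives negative ΔΔCT); a magnitude-style presentation
  (`reported_magnitude`, `reported_fold = 2^|ΔΔCT|`) matches the common
  practice of quoting an increase as a positive ΔΔCT. Only the magnitude is
  meaningful across conventions.

## Numerical and design choices

* All randomness flows from a single integer seed through per-stage
  `numpy` generators (`default_rng([stage, seed])`), so each stage is
  bit-reproducible and independent of how much randomness other stages
  consume.
* Fisher p-values come from `scipy.stats.hypergeom.sf`; the test suite
  checks them against an exhaustive exact-integer enumeration of every 2×2
  table with pool margins ≤ 40, and against `scipy.stats.fisher_exact` as a
  second, independent route.
* Ranking ties are broken lexicographically by gene id.
* Degenerate inputs raise `ValueError` early (empty formulas, zero pool
  totals, infeasible gene packing, CT values outside (0, 45), coincident
  leakage references).

## Known limitations

* The mapper is exact-match and in-memory; it is intended for synthetic
  genomes up to a few Mb. Real hg19-scale data should be aligned externally
  and imported via `import_external_alignments`.
* The published screen's exact p-values (e.g. 7.2 × 10⁻¹² for ETNK1) derive
  from ~100-million-cell experiments and are not recomputable at desk
  scale; the pipeline's statistical behaviour is validated by planted
  recovery and null calibration instead. `validate_source_counts` can
  reconcile per-gene counts against published supplementary tables when
  those files are available locally.
* The contingency construction uses unique inactivating *site* totals on
  both sides (not read totals), matching the description of the control
  library's 38,628 inactivating insertions entering the calculation.
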