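# haploscreen

Analysis of haploid gene-trap loss-of-function screens, from inverse-PCR
sequencing reads to per-gene enrichment statistics — plus the small defined
calculations that accompany such a screen when it uncovers a covalent drug
mechanism: Paal-Knorr adduct mass windows for LC-MS detection and common
assay quantifications (PE fraction, ¹⁴C flux, calcein leakage, viability,
ΔΔCT).

**Who it is for.** Groups running (or simulating) insertional-mutagenesis
screens in near-haploid human cells: a retroviral gene trap disrupts one
gene per haploid cell, drug selection enriches clones whose disrupted gene
confers resistance, and sequencing of provirus–genome junctions identifies
those genes. The package provides the full desk-side analysis and a
ground-truth simulator to validate it.

## The statistic at the core

For each annotated gene, inactivating insertions (exonic in any
orientation, or intronic in the sense orientation) are counted as unique
sites in the selected pool and in a pre-selection control library. The
enrichment p-value is the one-sided Fisher's exact test on

    [[k_sel, n_sel − k_sel],
     [k_ctrl, n_ctrl − k_ctrl]]

with `n_sel`, `n_ctrl` the genome-wide totals of inactivating sites in each
pool — equivalently the hypergeometric upper-tail sum P(X ≥ k_sel). Site
calling applies the protocol's filters first: reads are trimmed after the
first MseI/NlaIII site (TTAA/CATG), mapped with no mismatches to a single
alignment site, collapsed to unique sites, and sites 1–2 bp apart or
supported by a single read are discarded.

## Worked example

```python
import haploscreen as hs

cfg = hs.ScreenSimConfig(
    seed=1, n_chromosomes=2, chromosome_length=1_000_000,
    n_genes=100, n_insertions=50_000,
    resistance_genes=frozenset({"gene0010", "gene0050", "gene0090"}),
    p_survive_resistant=0.9, p_survive_background=0.001,
)
run = hs.run_screen(cfg)           # simulate -> map -> call -> classify -> Fisher
for r in hs.rank_genes(run.results)[:3]:
    print(r.gene_id, r.bubble_n, f"{r.p_value:.3g}")
```

prints

```
gene0010 50 9.11e-54
gene0090 43 2.06e-45
gene0050 44 1.31e-44
```

— the three planted resistance genes lead the ranking by many orders of
magnitude (`bubble_n` is the number of unique inactivating sites in the
resistant pool, the bubble diameter of the usual screen plot). The adduct
arithmetic side:

```python
from haploscreen.adducts import adduct_eic_window
w = adduct_eic_window("C25H36O4", "C2H7NO", ppm=5)   # ophiobolin A + ethanolamine
print(w.center, w.low, w.high)                        # 426.3003 426.2982 426.3024
```

the ±5 ppm extracted-ion-chromatogram window for the protonated
pyrrole adduct (addition product minus two waters, plus a proton).

The same steps are available as a CLI (`haploscreen simulate / map /
callsites / annotate / enrich / adduct-mz`) and as narrative drivers under
`analysis/` (01 simulate → 02 call and enrich → 03 adduct windows →
04 assay quantifications → 05 null calibration), which write their tables
under `results/` and their bulky intermediates under `scratch/`.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from molecular formulas through the package's mass arithmetic,
the EIC window bounds for the ophiobolin A–ethanolamine adduct, and runs a
seeded end-to-end screen as a sanity check, writing the reportable values
as JSON.

See `docs/methods.md` for the model, conventions (coordinates, strands,
depth distribution), numerical choices and known limitations.
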