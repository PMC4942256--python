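"""Worked examples of the assay quantifications on illustrative numbers.

PE fraction from phosphorus analysis, 14C flux normalized to phospholipid
content, calcein-leakage normalization between vehicle and detergent
references, viability normalization, and ddCT relative expression with a
GAPDH reference.
"""

import json
from pathlib import Path

from haploscreen.assays import (
    ddct_relative_expression,
    leakage_percent,
    pe_fraction,
    relative_flux,
    relative_viability,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out: dict = {}

    # Phosphorus split between the PE spot and all other phospholipid spots
    out["pe_fraction"] = pe_fraction(12.5, 37.5)
    print(f"PE content: 12.5 nmol Pi (PE) / 50 nmol total -> {out['pe_fraction']:.2f}")

    # 14C-PE counts per nmol total phospholipid, relative to vehicle
    out["relative_c14_flux"] = relative_flux(3200, 40, 1500, 50)
    print(f"14C flux vs vehicle: (3200/40) / (1500/50) -> {out['relative_c14_flux']:.2f}x")

    # Calcein leakage, normalized between DMSO (0%) and Triton (100%)
    t = [0, 30, 60]
    points = leakage_percent(t, [300, 420, 560], [100, 105, 110], [900, 905, 910])
    out["leakage_percent"] = [p.percent for p in points]
    print("leakage % over time:", ", ".join(f"{p.percent:.1f}" for p in points))

    # Viability of a treated well vs its vehicle control
    out["relative_viability"] = relative_viability(61_000, 122_000)
    print(f"relative viability: 61000/122000 -> {out['relative_viability']:.2f}")

    # ddCT, two primer pairs, GAPDH reference; magnitude-style presentation
    r = ddct_relative_expression([20.1, 20.3], [18.0, 18.1], [26.0, 26.5], [18.0, 18.1])
    out["ddct_magnitude"] = r.reported_magnitude
    out["ddct_fold"] = r.reported_fold
    print(f"ddCT magnitude {r.reported_magnitude:.2f} -> {r.reported_fold:.1f}-fold "
          "expression difference")

    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "assay_quantifications.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"values -> {OUT / 'assay_quantifications.json'}")


if __name__ == "__main__":
    main()
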