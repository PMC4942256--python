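"""Mass arithmetic for ophiobolin A-amine Paal-Knorr adducts.

Computes monoisotopic masses from molecular formulas, the neutral adduct
mass (addition minus two waters), the [M+H]+ m/z, and the +-5 ppm
extracted-ion-chromatogram window used to detect each adduct by LC-MS.
"""

from pathlib import Path

import pandas as pd

from haploscreen.adducts import (
    DIOLEOYL_PE_FORMULA,
    ETHANOLAMINE_FORMULA,
    OPA_FORMULA,
    adduct_eic_window,
    monoisotopic_mass,
    paal_knorr_adduct_mass,
    protonated_mz,
    round4,
)

OUT = Path(__file__).resolve().parent.parent / "results"

AMINES = {
    "ethanolamine": ETHANOLAMINE_FORMULA,
    "dioleoyl-PE": DIOLEOYL_PE_FORMULA,
}


def main() -> None:
    opa = monoisotopic_mass(OPA_FORMULA)
    print(f"ophiobolin A ({OPA_FORMULA}): exact mass {round4(opa):.4f} Da")
    rows = []
    for name, formula in AMINES.items():
        amine = monoisotopic_mass(formula)
        neutral = paal_knorr_adduct_mass(opa, amine)
        window = adduct_eic_window(OPA_FORMULA, formula, ppm=5)
        rows.append(
            {
                "amine": name,
                "amine_formula": formula,
                "amine_mass": round4(amine),
                "adduct_neutral": round4(neutral),
                "adduct_mz_h": round4(protonated_mz(neutral)),
                "eic_low": window.low,
                "eic_high": window.high,
            }
        )
        print(f"  {name}: exact mass {round4(amine):.4f}, adduct neutral "
              f"{round4(neutral):.4f}, [M+H]+ {round4(protonated_mz(neutral)):.4f}, "
              f"EIC window {window.low:.4f}-{window.high:.4f}")
    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "adduct_windows.tsv", sep="\t", index=False)
    print(f"table -> {OUT / 'adduct_windows.tsv'}")


if __name__ == "__main__":
    main()
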