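#!/usr/bin/env python
"""Convert optical-density readings of nucleotide preparations to amounts.

Uses the standard extinction coefficients (11.4 L/mmol/cm for
7-methylguanosine mononucleotides, 32.0 for trinucleotide cap analogs) to
turn measured mOD values into micromole amounts.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from capassays.io import write_table
from capassays.quantitation import quantitate_table

OUT = Path(__file__).resolve().parents[1] / "results"

# measured optical densities of three 7-methylguanosine triphosphate preps
MEASURED = pd.DataFrame({
    "compound": ["m7Gppp", "m7GppCH2p", "m7GppCCl2p"],
    "mOD": [12060.0, 3090.0, 3710.0],
    "epsilon": [11.4, 11.4, 11.4],
})


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = quantitate_table(MEASURED)
    table["amount_mmol"] = (table["amount_umol"] / 1000.0).round(3)
    write_table(table, OUT / "quantitation.csv")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
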