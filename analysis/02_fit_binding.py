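#!/usr/bin/env python
"""Recover cap-analog dissociation constants by simulated titration + fitting.

For a panel of measured K_D values spanning the tri- and tetraphosphate cap
analogs, simulates three replicate quenching titrations each under the study
protocol, fits the ligand-depletion model, pools by inverse variance, and
tabulates recovered vs true K_D.  Also reports the mean affinity gain of the
tetraphosphate caps over their triphosphate counterparts, computed from the
measured constants.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pandas as pd

from capassays.io import write_table
from capassays.pipeline import fit_binding_replicates

OUT = Path(__file__).resolve().parents[1] / "results"

# measured dissociation constants (nM) for matched methylation variants
PANEL = {
    "m7GpppApG": 35.5,
    "m7GpppAmpG": 42.1,
    "m7Gpppm6AmpG": 46.4,
    "m7GppppApG": 5.9,
    "m7GppppAmpG": 7.2,
    "m7Gppppm6AmpG": 7.3,
}
PAIRS = [("m7GpppApG", "m7GppppApG"),
         ("m7GpppAmpG", "m7GppppAmpG"),
         ("m7Gpppm6AmpG", "m7Gppppm6AmpG")]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (compound, kd_true) in enumerate(PANEL.items()):
        pooled, _ = fit_binding_replicates(
            kd_true, seeds=[100 * i + r for r in (1, 2, 3)], noise_scale=0.02)
        rows.append({
            "compound": compound, "kd_true_nM": kd_true,
            "kd_fit_nM": round(pooled.kd_nM, 2),
            "kd_se_nM": round(pooled.kd_se_nM, 2),
            "rel_error": round(abs(pooled.kd_nM - kd_true) / kd_true, 4),
        })
    table = pd.DataFrame(rows)
    write_table(table, OUT / "binding_panel.csv")
    print(table.to_string(index=False))

    ratios = [PANEL[a] / PANEL[b] for a, b in PAIRS]
    print(f"\nmean tetraphosphate affinity gain (measured K_D ratios): "
          f"{np.mean(ratios):.2f}-fold")
    worst = table["rel_error"].max()
    print(f"worst pooled recovery error across the panel: {100 * worst:.1f}%")


if __name__ == "__main__":
    main()
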