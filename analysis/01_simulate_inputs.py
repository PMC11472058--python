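#!/usr/bin/env python
"""Generate one synthetic input bundle for every assay the pipeline analyses.

Writes delimited tables plus ground-truth sidecars under results/simulated/:
a replicate set of fluorescence titrations for the reference cap (K_D
42.1 nM), a two-band gel lane at 90% capping, a first-order decapping time
course, a Gaussia-luciferase plate, and a TMT-9 protein-group table with
50 tetraphosphate-binder spikes.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from capassays import binding, synthetic
from capassays.io import write_table, write_truth_sidecar
from capassays.synthetic import SimulationConfig

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # three replicate titrations of the reference cap-1 trinucleotide
    aliquots, stocks = synthetic.escalating_stocks(42.1)
    protocol = binding.TitrationProtocol(aliquot_volumes=aliquots,
                                         stock_concs=stocks)
    params = binding.BindingModelParams(
        k_as=1000.0 / 42.1, p_act=0.1, f0=1000.0, delta_phi=9000.0,
        phi_free=10.0)
    for rep in (1, 2, 3):
        raw, truth = synthetic.gen_titration(
            params, protocol, SimulationConfig(seed=rep, noise_scale=0.02))
        write_table(raw, OUT / f"titration_rep{rep}.csv")
        write_truth_sidecar(truth, OUT / f"titration_rep{rep}.csv.truth")

    # gel lane: 9:1 capped:uncapped on a drifting baseline
    x, y, truth = synthetic.gen_lane_profile(
        [(30.0, 9.0, 2.0), (60.0, 1.0, 2.0)], baseline=(0.01, 0.0009),
        sim=SimulationConfig(seed=11, noise_scale=0.01))
    write_table(pd.DataFrame({"position": x, "intensity": y}),
                OUT / "lane_profile.csv")
    write_truth_sidecar(truth, OUT / "lane_profile.csv.truth")

    # decapping time course: 90% initially capped, ~77% decapped by 30 min
    table, truth = synthetic.gen_decapping_series(
        0.9, 0.05, sim=SimulationConfig(seed=21, noise_scale=0.02))
    write_table(table, OUT / "decapping.csv")
    write_truth_sidecar(truth, OUT / "decapping.csv.truth")

    # luciferase plate with a 1.32x analog and a near-silent tetraphosphate cap
    plate, truth = synthetic.gen_expression_plate(
        {"m7GpppAmpG": 1.0, "analog8": 1.32, "tetraphosphate": 0.02},
        sim=SimulationConfig(seed=31, noise_model="lognormal",
                             noise_scale=0.05))
    write_table(plate, OUT / "expression_plate.csv")
    write_truth_sidecar(truth, OUT / "expression_plate.csv.truth")

    # TMT-9 pull-down table with spiked tetraphosphate binders
    pg, truth = synthetic.gen_proteingroups(
        n_background=1000,
        spikes=[(["AR-2", "AR-3"], 2.5)] * 50,
        flags_rate={"reverse": 0.02, "contaminant": 0.02},
        missing_rate=0.02,
        sim=SimulationConfig(seed=41))
    write_table(pg, OUT / "proteingroups.tsv", dialect="generic_tsv")
    write_truth_sidecar(truth, OUT / "proteingroups.tsv.truth")

    print(f"wrote synthetic bundle under {OUT}")


if __name__ == "__main__":
    main()
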