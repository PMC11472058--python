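#!/usr/bin/env python
"""Capping efficiency and decapping susceptibility from simulated gel lanes.

Reads the synthetic bundle written by 01_simulate_inputs.py (generating it
if absent), integrates the lane profile, and computes the decapping time
course with the 30-minute susceptibility statistic.
"""

import subprocess
import sys
from pathlib import Path

HERE = Path(__file__).resolve().parent
sys.path.insert(0, str(HERE.parents[0] / "src"))

import pandas as pd

from capassays import densitometry
from capassays.io import read_table, read_truth_sidecar, write_table

SIM = HERE.parents[0] / "results" / "simulated"
OUT = HERE.parents[0] / "results"


def main() -> None:
    if not (SIM / "lane_profile.csv").exists():
        subprocess.run([sys.executable, str(HERE / "01_simulate_inputs.py")],
                       check=True)

    lane = read_table(SIM / "lane_profile.csv")
    truth = read_truth_sidecar(SIM / "lane_profile.csv.truth")
    bands = densitometry.integrate_bands(
        densitometry.LaneProfile(lane["position"].to_numpy(),
                                 lane["intensity"].to_numpy()))
    ce = densitometry.capping_efficiency(bands[0], bands[1])
    ce_true = truth["band_areas"][0] / sum(truth["band_areas"])
    print(f"capping efficiency: {100 * ce:.1f}% "
          f"(ground truth {100 * ce_true:.1f}%)")

    dec = read_table(SIM / "decapping.csv")
    series = {r.time_min: (r.capped, r.uncapped) for r in dec.itertuples()}
    course = densitometry.decapping_course(series)
    print(f"decapped at 30 min: {course.decapped_at_query:.2f}")

    write_table(pd.DataFrame({
        "time_min": course.timepoints_min,
        "capped_fraction": course.capped_fraction,
        "remaining": course.remaining,
    }), OUT / "decapping_course.csv")
    write_table(pd.DataFrame([{
        "capping_efficiency": ce,
        "decapped_at_30min": course.decapped_at_query,
    }]), OUT / "densitometry_summary.csv")


if __name__ == "__main__":
    main()
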