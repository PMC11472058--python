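"""Reporter-protein expression summaries from plate-reader time courses.

Secreted Gaussia luciferase accumulates in the medium between readings; the
medium is replaced at each timepoint, so each luminescence reading reflects
one inter-interval production window and the total over the schedule (default
16, 40, 64, 88 h) is a plain sum.  Totals are reported normalized to the mean
of a reference cap's replicates, so the reference itself comes out as
1 +/- CV by construction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SCHEDULE",
    "validate_expression_table",
    "cumulative_expression",
    "normalize_to_reference",
]

DEFAULT_SCHEDULE: tuple[float, ...] = (16.0, 40.0, 64.0, 88.0)

_REQUIRED = ("sample", "replicate", "timepoint_h", "luminescence")


def validate_expression_table(table: pd.DataFrame,
                              schedule=DEFAULT_SCHEDULE) -> pd.DataFrame:
    """Check a long-format luminescence table against the declared schedule."""
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"expression table missing columns {missing}")
    if (table["luminescence"] < 0).any():
        raise ValueError("luminescence must be >= 0")
    extra = set(table["timepoint_h"].unique()) - set(schedule)
    if extra:
        raise ValueError(f"timepoints {sorted(extra)} outside schedule {schedule}")
    return table


def cumulative_expression(table: pd.DataFrame,
                          schedule=DEFAULT_SCHEDULE) -> pd.DataFrame:
    """Per-replicate cumulative luminescence over the full schedule.

    Replicates missing any scheduled timepoint are excluded with a warning.
    Returns columns (sample[, cell_line], replicate, total).
    """
    validate_expression_table(table, schedule)
    keys = ["sample", "replicate"]
    if "cell_line" in table.columns:
        keys = ["cell_line", "sample", "replicate"]
    n_expected = len(schedule)
    grouped = table.groupby(keys, sort=False)
    counts = grouped["timepoint_h"].nunique()
    incomplete = counts[counts < n_expected]
    if len(incomplete):
        warnings.warn(
            f"excluding {len(incomplete)} replicate(s) with missing timepoints: "
            f"{list(incomplete.index)}", stacklevel=2)
    totals = grouped["luminescence"].sum().loc[counts[counts == n_expected].index]
    return totals.rename("total").reset_index()


def normalize_to_reference(
    totals: pd.DataFrame,
    reference_sample: str,
    by: str | None = "cell_line",
) -> pd.DataFrame:
    """Normalize replicate totals to the reference sample's mean total.

    Division is by the reference *mean* within each ``by`` group (per cell
    line by default; pass ``by=None`` to pool), so the reference reports as
    mean 1 with SD equal to its coefficient of variation.  Returns one row
    per sample: (sample[, cell_line], n, normalized_mean, normalized_sd).
    """
    if by is not None and by not in totals.columns:
        by = None
    group_cols = [by] if by else []

    out_rows = []
    for key, sub in (totals.groupby(by) if by else [(None, totals)]):
        ref = sub.loc[sub["sample"] == reference_sample, "total"]
        if len(ref) == 0:
            raise ValueError(
                f"reference sample {reference_sample!r} absent"
                + (f" in {by}={key!r}" if by else ""))
        ref_mean = float(ref.mean())
        if ref_mean == 0:
            raise ValueError("reference mean total is zero")
        for sample, ss in sub.groupby("sample", sort=False):
            norm = ss["total"].to_numpy(float) / ref_mean
            row = {"sample": sample, "n": len(norm),
                   "normalized_mean": float(np.mean(norm)),
                   "normalized_sd": float(np.std(norm, ddof=1)) if len(norm) > 1
                   else float("nan")}
            if by:
                row[by] = key
            out_rows.append(row)
    cols = group_cols + ["sample", "n", "normalized_mean", "normalized_sd"]
    return pd.DataFrame(out_rows)[cols]
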