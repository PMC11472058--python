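"""Spectrophotometric nucleotide quantitation.

Nucleotide amounts are tracked as optical density units, mOD = absorbance of
the solution x volume in mL.  With an extinction coefficient eps in
L mmol^-1 cm^-1 and a path length in cm, the molar amount follows directly
from Beer's law:

    amount [umol] = mOD / (eps * path)

Typical coefficients at 260 nm: 32.0 for trinucleotide cap analogs, 27.1 for
A/G dinucleotides, 11.4 for 7-methylguanosine mononucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["OpticalMeasure", "amount_from_mOD", "percent_yield", "quantitate_table"]


@dataclass(frozen=True)
class OpticalMeasure:
    """An mOD reading with its extinction coefficient and path length."""

    mOD: float
    epsilon: float
    path_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.mOD < 0:
            raise ValueError(f"mOD must be >= 0, got {self.mOD}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.path_cm <= 0:
            raise ValueError(f"path_cm must be > 0, got {self.path_cm}")


def amount_from_mOD(m: OpticalMeasure) -> float:
    """Molar amount in umol from an optical-density measurement."""
    return m.mOD / (m.epsilon * m.path_cm)


def percent_yield(product_umol: float, start_umol: float) -> float:
    """Synthesis yield as 100 * product / start.

    Values above 100% are possible with inconsistent inputs and are returned
    as-is; callers wanting a flag can compare against 100.
    """
    if start_umol <= 0:
        raise ValueError("start amount must be > 0")
    if product_umol < 0:
        raise ValueError("product amount must be >= 0")
    return 100.0 * product_umol / start_umol


def quantitate_table(table: pd.DataFrame, path_cm: float = 1.0) -> pd.DataFrame:
    """Vectorized quantitation of a (compound, mOD, epsilon[, start_umol]) table.

    Adds ``amount_umol`` and, where ``start_umol`` is present, ``yield_percent``.
    """
    for col in ("mOD", "epsilon"):
        if col not in table.columns:
            raise ValueError(f"missing required column {col!r}")
    out = table.copy()
    if (out["mOD"] < 0).any() or (out["epsilon"] <= 0).any():
        raise ValueError("mOD must be >= 0 and epsilon > 0")
    out["amount_umol"] = out["mOD"] / (out["epsilon"] * path_cm)
    if "start_umol" in out.columns:
        out["yield_percent"] = 100.0 * out["amount_umol"] / out["start_umol"]
    return out
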