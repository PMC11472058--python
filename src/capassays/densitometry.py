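"""Lane-profile densitometry: band integration, capping efficiency, decapping.

A polyacrylamide gel lane is reduced to a 1-D trace of intensity versus
migration coordinate.  Capped and uncapped transcripts differ by a couple of
nucleotides (plus the cap's extra charge) and resolve as neighbouring bands;
the capping efficiency is the capped band's share of the capped+uncapped
signal.  The same band pair tracked across a Dcp2 digestion time course gives
the decapping susceptibility: one minus the remaining capped fraction,
normalized to the t=0 capped fraction so incomplete initial capping does not
inflate apparent decapping.

Band quantification: a slowly varying baseline is estimated by asymmetric
least squares (heavier penalty on points above the baseline, so peaks do not
drag it up), peaks are located by prominence on the baseline-subtracted
trace, and each peak is integrated between its flanking valley minima.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, sparse
from scipy.sparse.linalg import spsolve

__all__ = [
    "LaneProfile",
    "BandQuant",
    "DecappingSeries",
    "als_baseline",
    "integrate_bands",
    "capping_efficiency",
    "decapping_course",
    "replicate_summary",
]


@dataclass(frozen=True)
class LaneProfile:
    """A densitometric trace: strictly monotone positions and signal."""

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.positions, float)
        y = np.asarray(self.intensities, float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("positions and intensities must be equal-length 1-D")
        if np.any(np.diff(x) <= 0):
            raise ValueError("positions must be strictly increasing")
        object.__setattr__(self, "positions", x)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class BandQuant:
    """One integrated band: label, apex position and area above baseline."""

    band_id: str
    position: float
    area: float
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("band area must be >= 0")


def als_baseline(y, lam: float = 1e8, p: float = 0.001, n_iter: int = 10):
    """Asymmetric-least-squares baseline of a 1-D trace.

    Minimizes sum(w_i (y_i - z_i)^2) + lam * sum((d2 z)^2) with weights p for
    points above the current baseline and 1-p below, iterated ``n_iter``
    times.  ``lam`` controls stiffness, ``p`` the asymmetry.
    """
    y = np.asarray(y, float)
    n = len(y)
    if n < 3:
        return np.zeros_like(y)
    d = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2))
    dd = lam * (d @ d.T)
    w = np.ones(n)
    z = y.copy()
    for _ in range(n_iter):
        W = sparse.diags(w)
        z = spsolve((W + dd).tocsc(), w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def integrate_bands(
    profile: LaneProfile,
    *,
    prominence_frac: float = 0.05,
    lam: float = 1e8,
    p: float = 0.001,
    subtract_baseline: bool = True,
    saturation_level: float | None = None,
) -> list[BandQuant]:
    """Detect and integrate bands in a lane profile.

    Peaks are local maxima of the baseline-subtracted trace with prominence at
    least ``prominence_frac`` of its dynamic range; each is integrated
    (trapezoid) between the flanking valley minima.  Returns bands sorted by
    position; an empty list when the trace is flat.
    """
    x, y = profile.positions, profile.intensities
    base = als_baseline(y, lam=lam, p=p) if subtract_baseline else np.zeros_like(y)
    r = y - base
    span = float(np.ptp(r))
    if span <= 0:
        return []
    peaks, _props = signal.find_peaks(r, prominence=prominence_frac * span)
    bands: list[BandQuant] = []
    for j, pk in enumerate(peaks):
        lo = peaks[j - 1] if j > 0 else 0
        hi = peaks[j + 1] if j + 1 < len(peaks) else len(r) - 1
        left = lo + int(np.argmin(r[lo:pk + 1]))
        right = pk + int(np.argmin(r[pk:hi + 1]))
        seg = slice(left, right + 1)
        area = float(np.trapezoid(np.clip(r[seg], 0.0, None), x[seg]))
        saturated = bool(
            saturation_level is not None and np.any(y[seg] >= saturation_level)
        )
        bands.append(BandQuant(f"band_{j}", float(x[pk]), area, saturated))
    return sorted(bands, key=lambda b: b.position)


def capping_efficiency(capped: BandQuant, uncapped: BandQuant) -> float:
    """Capped fraction = capped / (capped + uncapped) band areas."""
    total = capped.area + uncapped.area
    if total <= 0:
        raise ValueError("capped and uncapped areas are both zero")
    return capped.area / total


@dataclass(frozen=True)
class DecappingSeries:
    """Capped fraction versus time plus the derived susceptibility statistic."""

    timepoints_min: np.ndarray
    capped_fraction: np.ndarray
    remaining: np.ndarray  # normalized to t=0
    query_time_min: float
    decapped_at_query: float

    def __post_init__(self) -> None:
        cf = np.asarray(self.capped_fraction, float)
        if np.any((cf < 0) | (cf > 1)):
            raise ValueError("capped fractions must lie in [0, 1]")


def decapping_course(
    series: dict[float, tuple[BandQuant, BandQuant]] | dict[float, tuple[float, float]],
    query_time_min: float = 30.0,
) -> DecappingSeries:
    """Decapping time course from per-timepoint (capped, uncapped) band pairs.

    ``series`` maps time in minutes to a (capped, uncapped) pair of
    ``BandQuant`` or raw areas.  The capped fraction cf(t) is computed per
    timepoint, the remaining fraction cf(t)/cf(0), and the susceptibility
    statistic ``decapped_at_query = 1 - remaining(query)`` clipped to [0, 1].
    Timepoint 0 and the query time must both be present (no interpolation).
    """
    times = np.array(sorted(series.keys()), float)
    if np.any(times < 0):
        raise ValueError("negative timepoints")
    if 0.0 not in times:
        raise ValueError("timepoint 0 is required")
    if query_time_min not in times:
        raise ValueError(f"query time {query_time_min} min absent from series")

    def _area(b):
        return b.area if isinstance(b, BandQuant) else float(b)

    cf = []
    for t in times:
        capped, uncapped = series[t]
        a_c, a_u = _area(capped), _area(uncapped)
        if a_c + a_u <= 0:
            raise ValueError(f"zero total band intensity at t={t}")
        cf.append(a_c / (a_c + a_u))
    cf = np.array(cf)
    if cf[0] <= 0:
        raise ValueError("capped fraction at t=0 is zero; cannot normalize")
    remaining = cf / cf[0]
    if np.any(remaining > 1):
        warnings.warn("remaining capped fraction exceeds 1 (noise); clipping",
                      stacklevel=2)
    remaining = np.clip(remaining, 0.0, 1.0)
    idx = int(np.where(times == query_time_min)[0][0])
    return DecappingSeries(
        timepoints_min=times,
        capped_fraction=cf,
        remaining=remaining,
        query_time_min=query_time_min,
        decapped_at_query=float(1.0 - remaining[idx]),
    )


def replicate_summary(values) -> tuple[float, float]:
    """Mean and sample SD (ddof=1) of replicate fractions.

    A single value returns (value, nan) so callers can flag undefined spread.
    """
    v = np.asarray(list(values), float)
    if len(v) == 0:
        raise ValueError("no values")
    if len(v) == 1:
        return float(v[0]), math.nan
    return float(np.mean(v)), float(np.std(v, ddof=1))
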