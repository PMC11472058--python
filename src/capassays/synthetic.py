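"""Synthetic data generators mirroring every assay the pipeline analyses.

Each generator forward-simulates the measurement process that the matching
analysis stage inverts, so a noiseless generation composed with its analysis
stage is the identity on the ground-truth parameters (up to solver
tolerance).  Ground truth is always returned alongside the data so recovery
tests never have to re-derive it.

Defaults encode the study conditions: titrations add 1 ul aliquots of
escalating ligand stocks to 1.4 ml of 0.1 uM protein; gel lanes are Gaussian
bands on a drifting baseline; decapping is first-order over 0/5/15/30/60 min;
luminescence is log-normally noisy over the 16/40/64/88 h schedule; and the
pull-down table is a TMT-9 log-normal intensity matrix with spiked group
effects, missing values and decoy/contaminant rows.  Measurement noise
magnitudes are conventions chosen to be realistic for the instruments
involved (2% relative for the spectrofluorometer, 1% for gel densitometry,
5-20% CV for luminescence), since such figures are rarely reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binding import (
    BindingModelParams,
    TitrationProtocol,
    inner_filter_factor,
    model_fluorescence,
)
from .proteomics import CHANNEL_GROUPS, channel_columns

__all__ = [
    "SimulationConfig",
    "escalating_stocks",
    "gen_titration",
    "gen_lane_profile",
    "gen_decapping_series",
    "gen_expression_plate",
    "gen_proteingroups",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Seeded noise model: identical config => bitwise-identical output."""

    seed: int = 0
    noise_model: str = "gaussian_relative"
    noise_scale: float = 0.02

    def __post_init__(self) -> None:
        if self.noise_model not in ("gaussian_relative", "gaussian_absolute",
                                    "lognormal"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, signal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Add noise to a clean signal (new array; zero scale is a no-op)."""
        signal = np.asarray(signal, float)
        if self.noise_scale == 0:
            return signal.copy()
        if self.noise_model == "gaussian_relative":
            return signal * (1.0 + self.noise_scale * rng.standard_normal(signal.shape))
        if self.noise_model == "gaussian_absolute":
            return signal + self.noise_scale * rng.standard_normal(signal.shape)
        # lognormal: multiplicative with median 1 and log-sd = noise_scale
        return signal * rng.lognormal(0.0, self.noise_scale, signal.shape)


def escalating_stocks(
    kd_nM: float,
    n_points: int = 45,
    *,
    lo: float = 0.1,
    hi: float = 20.0,
    protein_conc: float = 0.1,
    start_volume: float = 1400.0,
    aliquot_ul: float = 1.0,
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Design escalating stock concentrations for a fixed-aliquot titration.

    Returns (aliquot_volumes, stock_concs) in ul and uM such that the total
    ligand concentration after each of the ``n_points`` aliquots lands on a
    log-spaced grid from ``lo`` x K_D up to ``hi`` x K_D — extended, for
    tight binders, to at least 4 x the protein concentration so the
    titration always crosses the stoichiometric point into saturation.
    A third of the points sit below 0.3 x protein concentration (pinning the
    initial level and slope); the rest cover the binding transition through
    saturation, where the curvature carries the affinity information.  The
    default 45 one-ul additions keep the total dilution under 4%, matching
    spectrofluorometric practice.
    """
    if n_points < 6:
        raise ValueError("need at least 6 aliquots for a fittable curve")
    kd_uM = kd_nM / 1000.0
    top = max(hi * kd_uM, 4.0 * protein_conc)
    knee = 0.3 * protein_conc
    if lo * kd_uM < knee < top:
        n1 = n_points // 3
        targets = np.concatenate([
            np.geomspace(lo * kd_uM, knee, n1, endpoint=False),
            np.geomspace(knee, top, n_points - n1),
        ])
    else:
        targets = np.geomspace(lo * kd_uM, top, n_points)
    stocks = []
    delivered = 0.0  # cumulative c*v, uM*ul
    vol = start_volume
    for L_target in targets:
        vol += aliquot_ul
        c = (L_target * vol - delivered) / aliquot_ul
        if c <= 0:
            raise ValueError("target ligand grid is not achievable (non-monotone)")
        stocks.append(c)
        delivered += c * aliquot_ul
    return (aliquot_ul,) * n_points, tuple(stocks)


def gen_titration(
    true_params: BindingModelParams,
    protocol: TitrationProtocol,
    sim: SimulationConfig,
) -> tuple[pd.DataFrame, dict]:
    """Simulate one raw titration table under the quenching model.

    The clean fluorescence at each point uses the per-point diluted ligand and
    protein concentrations; the *observed* value is the clean one divided by
    the dilution factor and the inner-filter factor (the exact inverse of the
    corrections that ``build_curve`` applies), then noised.  Row 0 is the
    ligand-free protein reading.

    Returns (raw table with aliquot_ul, stock_uM, f_obs columns; ground-truth
    sidecar dict).
    """
    sched = protocol.schedule()
    L = sched["ligand_uM"].to_numpy()
    P = sched["protein_uM"].to_numpy()
    V = sched["volume_ul"].to_numpy()
    f_true = model_fluorescence(L, true_params, p_act=P)
    f_obs_clean = f_true * (protocol.start_volume / V) / inner_filter_factor(L, protocol)
    f_obs = sim.apply(f_obs_clean, sim.rng())
    raw = pd.DataFrame({
        "aliquot_ul": np.concatenate([[0.0], protocol.aliquot_volumes]),
        "stock_uM": np.concatenate([[0.0], protocol.stock_concs]),
        "f_obs": f_obs,
    })
    truth = {
        "k_as": true_params.k_as, "kd_nM": true_params.kd_nM,
        "p_act": true_params.p_act, "f0": true_params.f0,
        "delta_phi": true_params.delta_phi, "phi_free": true_params.phi_free,
        "seed": sim.seed,
    }
    return raw, truth


def gen_lane_profile(
    bands: list[tuple[float, float, float]],
    baseline: tuple[float, ...] = (0.0,),
    sim: SimulationConfig = SimulationConfig(noise_scale=0.01),
    n_points: int = 1000,
    x_range: tuple[float, float] = (0.0, 100.0),
):
    """Simulate a gel lane as Gaussian bands on a polynomial baseline.

    ``bands`` is a list of (position, area, width-sigma) tuples;
    ``baseline`` holds polynomial coefficients in increasing order
    (numpy.polynomial convention).  Noise is applied to the full trace.
    Returns (positions, intensities, truth dict with the input band areas).
    """
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    lo, hi = x_range
    for pos, area, width in bands:
        if area < 0:
            raise ValueError("band areas must be >= 0")
        if width <= 0:
            raise ValueError("band widths must be > 0")
        if not (lo <= pos <= hi):
            raise ValueError(f"band position {pos} outside trace range {x_range}")
    x = np.linspace(lo, hi, n_points)
    y = np.polynomial.polynomial.polyval(x, np.asarray(baseline, float))
    for pos, area, width in bands:
        y = y + area / (width * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((x - pos) / width) ** 2)
    y_noisy = sim.apply(y, sim.rng())
    truth = {"band_areas": [b[1] for b in bands],
             "band_positions": [b[0] for b in bands], "seed": sim.seed}
    return x, y_noisy, truth


def gen_decapping_series(
    initial_capped_fraction: float,
    rate_per_min: float,
    timepoints_min=(0.0, 5.0, 15.0, 30.0, 60.0),
    sim: SimulationConfig = SimulationConfig(noise_scale=0.0),
    total_intensity: float = 1000.0,
) -> tuple[pd.DataFrame, dict]:
    """First-order decapping time course as per-timepoint band intensities.

    Capped fraction decays as cf(t) = cf(0) * exp(-rate * t); per lane the
    capped and uncapped band intensities sum to ``total_intensity`` before
    noise.  Returns (table with time_min, capped, uncapped columns; truth).
    """
    if not 0.0 <= initial_capped_fraction <= 1.0:
        raise ValueError("initial_capped_fraction must be in [0, 1]")
    if rate_per_min < 0:
        raise ValueError("rate must be >= 0")
    t = np.asarray(timepoints_min, float)
    if np.any(t < 0):
        raise ValueError("negative timepoints")
    cf = initial_capped_fraction * np.exp(-rate_per_min * t)
    rng = sim.rng()
    capped = sim.apply(total_intensity * cf, rng)
    uncapped = sim.apply(total_intensity * (1.0 - cf), rng)
    table = pd.DataFrame({"time_min": t, "capped": capped, "uncapped": uncapped})
    truth = {"capped_fraction": cf, "rate_per_min": rate_per_min,
             "initial_capped_fraction": initial_capped_fraction, "seed": sim.seed}
    return table, truth


def gen_expression_plate(
    true_relative_levels: dict[str, float],
    timecourse_shape=(0.35, 0.30, 0.20, 0.15),
    n_replicates: int = 3,
    sim: SimulationConfig = SimulationConfig(noise_model="lognormal", noise_scale=0.05),
    reference_sample: str = "m7GpppAmpG",
    schedule=(16.0, 40.0, 64.0, 88.0),
    base_rlu: float = 1e5,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a luminescence plate over the reading schedule.

    Each reading is level x shape-weight x base RLU, times a multiplicative
    noise factor.  The reference sample must be present with level 1.0.
    Returns a long-format table (sample, replicate, timepoint_h, luminescence)
    and the ground-truth levels.
    """
    if not true_relative_levels:
        raise ValueError("sample map is empty")
    if true_relative_levels.get(reference_sample) != 1.0:
        raise ValueError(
            f"reference sample {reference_sample!r} must be present with level 1.0")
    if len(timecourse_shape) != len(schedule):
        raise ValueError("timecourse_shape must match the schedule length")
    rng = sim.rng()
    rows = []
    for sample, level in true_relative_levels.items():
        for rep in range(1, n_replicates + 1):
            clean = level * base_rlu * np.asarray(timecourse_shape, float)
            lum = sim.apply(clean, rng)
            for tp, v in zip(schedule, lum):
                rows.append({"sample": sample, "replicate": rep,
                             "timepoint_h": tp, "luminescence": max(float(v), 0.0)})
    truth = {"levels": dict(true_relative_levels),
             "reference": reference_sample, "seed": sim.seed}
    return pd.DataFrame(rows), truth


def gen_proteingroups(
    n_background: int = 1000,
    spikes: list[tuple[str, float]] | None = None,
    *,
    flags_rate: dict[str, float] | None = None,
    missing_rate: float = 0.0,
    sigma: float = 0.5,
    baseline_log2_mean: float = 20.0,
    baseline_log2_sd: float = 2.0,
    sim: SimulationConfig = SimulationConfig(),
) -> tuple[pd.DataFrame, dict]:
    """Simulate a TMT-9 protein-group table with known differential spikes.

    Background rows have log2 intensities drawn around a per-protein baseline
    with channel noise ``sigma`` (log2 units).  Each ``spikes`` entry
    ``(group, log2fc)`` adds one row shifted by ``log2fc`` in the stated
    resin's three channels (group in {"AR-1", "AR-2", "AR-3"}; a list of
    groups spikes several at once).  ``flags_rate`` gives per-row Bernoulli
    probabilities for the decoy / site-only / contaminant annotations on
    background rows (spiked rows are never flagged); ``missing_rate`` masks
    reporter values completely at random.  Razor+unique peptide counts are
    sampled >= 1.

    Returns (table in the pipeline's column dialect; truth dict with the
    spiked row ids per group).
    """
    spikes = list(spikes or [])
    flags_rate = dict(flags_rate or {})
    for key in flags_rate:
        if key not in ("reverse", "site_only", "contaminant"):
            raise ValueError(f"unknown flag kind {key!r}")
    rng = sim.rng()
    cols = channel_columns()
    groups = np.array(CHANNEL_GROUPS)

    def _make_rows(n, prefix):
        base = rng.normal(baseline_log2_mean, baseline_log2_sd, n)
        log2 = base[:, None] + rng.normal(0.0, sigma, (n, 9))
        return log2

    ids, log2_rows, flag_rows, spiked_by_group = [], [], [], {}
    # background rows carry the QC flags, drawn per row and flag kind
    log2 = _make_rows(n_background, "bg")
    p_rev = flags_rate.get("reverse", 0.0)
    p_site = flags_rate.get("site_only", 0.0)
    p_cont = flags_rate.get("contaminant", 0.0)
    draws = rng.random((n_background, 3))
    for i in range(n_background):
        ids.append(f"BG{i:05d}")
        flag_rows.append((draws[i, 0] < p_rev, draws[i, 1] < p_site,
                          draws[i, 2] < p_cont))
    log2_rows.append(log2)
    # spikes
    if spikes:
        sp = _make_rows(len(spikes), "sp")
        for j, (grp, fc) in enumerate(spikes):
            targets = grp if isinstance(grp, (list, tuple)) else [grp]
            for g in targets:
                if g not in ("AR-1", "AR-2", "AR-3"):
                    raise ValueError(f"unknown spike group {g!r}")
                sp[j, groups == g] += fc
                spiked_by_group.setdefault(g, []).append(f"SP{j:05d}")
            ids.append(f"SP{j:05d}")
            flag_rows.append((False, False, False))
        log2_rows.append(sp)

    log2_all = np.vstack(log2_rows)
    intens = 2.0 ** log2_all
    if missing_rate > 0:
        mask = rng.random(intens.shape) < missing_rate
        intens = np.where(mask, np.nan, intens)

    n_rows = len(ids)
    table = pd.DataFrame(intens, columns=cols)
    table.insert(0, "group_id", ids)
    # >= 2 so clean, unflagged, complete rows pass the default razor filter
    table["razor_unique_peptides"] = 2 + rng.poisson(3.0, n_rows)
    table["ibaq"] = 2.0 ** (log2_all.mean(axis=1) - 10.0)
    fr = np.array(flag_rows, bool)
    table["flag_reverse"] = fr[:, 0]
    table["flag_site_only"] = fr[:, 1]
    table["flag_contaminant"] = fr[:, 2]
    truth = {"spiked": {g: sorted(v) for g, v in spiked_by_group.items()},
             "n_background": n_background, "seed": sim.seed}
    return table, truth
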