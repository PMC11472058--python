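"""Fluorescence-quenching titration analysis of cap analog binding to eIF4E.

eIF4E's intrinsic tryptophan fluorescence is quenched when a 7-methylguanosine
cap analog occupies the cap-binding slot.  A titration adds microlitre aliquots
of increasingly concentrated ligand stock to a cuvette of protein and records
fluorescence after each addition.  Because the protein concentration (~0.1 uM)
is comparable to the dissociation constants being measured (tens of nM), the
free-ligand approximation fails and the model must account for ligand
depletion: the complex concentration is the physical root of the 1:1 binding
quadratic.

The observed signal model is

    F(L) = F0 - [cx] * (dPhi + Phi_free) + L * Phi_free

where ``[cx]`` is the equilibrium complex concentration at total ligand ``L``
and total active protein ``P_act``, ``dPhi`` the difference between the
fluorescence efficiencies of apo and bound protein, ``Phi_free`` the
fluorescence efficiency of free ligand, and ``F0`` the pre-titration reading.
Association constants from replicate titrations are pooled by inverse-variance
weighting and reported as dissociation constants in nM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import lmfit

__all__ = [
    "BindingModelParams",
    "TitrationProtocol",
    "TitrationCurve",
    "BindingFitResult",
    "PooledBinding",
    "complex_concentration",
    "model_fluorescence",
    "build_curve",
    "fit_titration",
    "pool_replicates",
]


@dataclass(frozen=True)
class BindingModelParams:
    """Parameters of the ligand-depletion quenching model.

    k_as : association constant, 1/uM
    p_act : total active protein concentration, uM
    f0 : initial (ligand-free) fluorescence, arbitrary units
    delta_phi : apo-minus-bound fluorescence efficiency difference, units/uM
    phi_free : fluorescence efficiency of the free ligand, units/uM
    """

    k_as: float
    p_act: float
    f0: float
    delta_phi: float
    phi_free: float = 0.0

    def __post_init__(self) -> None:
        if self.k_as <= 0:
            raise ValueError(f"k_as must be > 0, got {self.k_as}")
        if self.p_act < 0:
            raise ValueError(f"p_act must be >= 0, got {self.p_act}")
        if self.phi_free < 0:
            raise ValueError(f"phi_free must be >= 0, got {self.phi_free}")

    @property
    def kd_nM(self) -> float:
        """Dissociation constant in nM (k_as is in 1/uM)."""
        return 1000.0 / self.k_as


@dataclass(frozen=True)
class TitrationProtocol:
    """Physical layout of one titration experiment.

    Volumes in ul, concentrations in uM.  ``eps_ex``/``eps_em`` are ligand
    extinction coefficients (L mmol^-1 cm^-1) at the excitation and emission
    wavelengths, used for the inner-filter correction with the cuvette's
    absorption/emission path lengths in cm (defaults 0.4 and 1.0 cm, i.e. a
    4 x 10 mm semi-micro cuvette).
    """

    start_volume: float = 1400.0
    protein_conc0: float = 0.1
    aliquot_volumes: tuple[float, ...] = ()
    stock_concs: tuple[float, ...] = ()
    eps_ex: float = 0.0
    eps_em: float = 0.0
    path_ex: float = 0.4
    path_em: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "aliquot_volumes", tuple(self.aliquot_volumes))
        object.__setattr__(self, "stock_concs", tuple(self.stock_concs))
        if len(self.aliquot_volumes) != len(self.stock_concs):
            raise ValueError(
                "aliquot_volumes and stock_concs must have equal length "
                f"({len(self.aliquot_volumes)} vs {len(self.stock_concs)})"
            )
        vals = (self.start_volume, self.protein_conc0, *self.aliquot_volumes,
                *self.stock_concs)
        if any(v < 0 for v in vals):
            raise ValueError("volumes and concentrations must be >= 0")
        if self.start_volume == 0:
            raise ValueError("start_volume must be positive")

    @property
    def n_points(self) -> int:
        """Number of readings, including the ligand-free point 0."""
        return len(self.aliquot_volumes) + 1

    def schedule(self) -> pd.DataFrame:
        """Cumulative volume, total ligand and protein at every reading.

        Returns a frame with columns ``volume_ul``, ``ligand_uM`` and
        ``protein_uM``; row 0 is the pre-titration state.
        """
        v = np.concatenate([[0.0], np.asarray(self.aliquot_volumes, float)])
        c = np.concatenate([[0.0], np.asarray(self.stock_concs, float)])
        vol = self.start_volume + np.cumsum(v)
        ligand = np.cumsum(c * v) / vol
        protein = self.protein_conc0 * self.start_volume / vol
        return pd.DataFrame(
            {"volume_ul": vol, "ligand_uM": ligand, "protein_uM": protein}
        )


@dataclass(frozen=True)
class TitrationCurve:
    """Dilution- and inner-filter-corrected titration data for one replicate.

    ``ligand_uM`` is total ligand, ``f_corrected`` the corrected fluorescence
    and ``protein_uM`` the (diluted) total protein at each point.
    """

    ligand_uM: np.ndarray
    f_corrected: np.ndarray
    protein_uM: np.ndarray
    protocol: TitrationProtocol | None = None

    def __post_init__(self) -> None:
        L = np.asarray(self.ligand_uM, float)
        F = np.asarray(self.f_corrected, float)
        P = np.asarray(self.protein_uM, float)
        if not (L.shape == F.shape == P.shape):
            raise ValueError("curve arrays must have equal shape")
        if np.any(np.diff(L) < 0):
            raise ValueError("total ligand must be non-decreasing")
        if np.any(L < 0) or np.any(P < 0):
            raise ValueError("concentrations must be >= 0")
        object.__setattr__(self, "ligand_uM", L)
        object.__setattr__(self, "f_corrected", F)
        object.__setattr__(self, "protein_uM", P)

    def __len__(self) -> int:
        return len(self.ligand_uM)


def complex_concentration(L, p_act, k_as):
    """Equilibrium 1:1 complex concentration under ligand depletion.

    Solves ``k_as * (L - cx) * (P - cx) = cx`` for the physical root

        cx = (L + P)/2 + (1 - sqrt((k_as (L - P) + 1)^2 + 4 k_as P)) / (2 k_as)

    All concentrations in uM, ``k_as`` in 1/uM.  Vectorized over ``L`` and
    ``p_act`` (broadcast).  ``k_as == 0`` is accepted as the no-binding limit
    (cx = 0).
    """
    scalar = np.isscalar(L) and np.isscalar(p_act)
    L = np.asarray(L, dtype=float)
    P = np.asarray(p_act, dtype=float)
    if np.any(L < 0) or np.any(P < 0):
        raise ValueError("concentrations must be >= 0")
    if k_as < 0:
        raise ValueError("k_as must be >= 0")
    if k_as == 0:
        cx = np.zeros(np.broadcast_shapes(L.shape, P.shape))
    else:
        # the displayed form (L+P)/2 + (1 - sqrt(disc))/(2K) cancels
        # catastrophically when cx << L+P; the algebraically identical
        # small-root formulation 2c / (b + sqrt(b^2 - 4ac)) is stable
        b = k_as * (L + P) + 1.0
        disc = (k_as * (L - P) + 1.0) ** 2 + 4.0 * k_as * P  # == b^2 - 4 K^2 L P
        cx = 2.0 * k_as * L * P / (b + np.sqrt(disc))
        # guard tiny round-off at the boundaries
        cx = np.clip(cx, 0.0, np.minimum(L, P))
    return float(cx) if scalar else cx


def model_fluorescence(L, params: BindingModelParams, p_act=None):
    """Predicted fluorescence at total ligand ``L``.

    ``p_act`` overrides the protein concentration pointwise (e.g. the diluted
    per-point values from a protocol schedule); by default ``params.p_act``
    is used throughout.
    """
    p = params.p_act if p_act is None else p_act
    cx = complex_concentration(L, p, params.k_as)
    L = np.asarray(L, dtype=float) if not np.isscalar(L) else L
    return params.f0 - cx * (params.delta_phi + params.phi_free) + L * params.phi_free


def inner_filter_factor(L_uM, protocol: TitrationProtocol):
    """Multiplicative inner-filter correction 10**((A_ex + A_em)/2).

    Absorbances are computed from the ligand alone: A = eps * [L] * path with
    eps in L mmol^-1 cm^-1 and [L] converted from uM to mM.
    """
    L_mM = np.asarray(L_uM, dtype=float) / 1000.0
    a_ex = protocol.eps_ex * L_mM * protocol.path_ex
    a_em = protocol.eps_em * L_mM * protocol.path_em
    return 10.0 ** ((a_ex + a_em) / 2.0)


def build_curve(raw: pd.DataFrame, protocol: TitrationProtocol) -> TitrationCurve:
    """Correct a raw titration table for dilution and the inner-filter effect.

    ``raw`` must contain a ``f_obs`` column with ``protocol.n_points`` rows
    (row 0 = ligand-free reading).  Corrected fluorescence is

        F_corr = F_obs * (V_i / V0) * 10**((A_ex + A_em)/2)

    which undoes both the dilution of the fluorophore and the attenuation of
    excitation/emission light by the absorbing titrant.
    """
    if "f_obs" not in raw.columns:
        raise ValueError("raw titration table must have a 'f_obs' column")
    if len(raw) != protocol.n_points:
        raise ValueError(
            f"raw table has {len(raw)} rows; protocol defines {protocol.n_points} points"
        )
    sched = protocol.schedule()
    dilution = sched["volume_ul"].to_numpy() / protocol.start_volume
    iff = inner_filter_factor(sched["ligand_uM"].to_numpy(), protocol)
    f_corr = raw["f_obs"].to_numpy(dtype=float) * dilution * iff
    return TitrationCurve(
        ligand_uM=sched["ligand_uM"].to_numpy(),
        f_corrected=f_corr,
        protein_uM=sched["protein_uM"].to_numpy(),
        protocol=protocol,
    )


@dataclass(frozen=True)
class BindingFitResult:
    """One replicate's least-squares fit."""

    params: BindingModelParams
    se: dict[str, float]
    ssr: float
    n_points: int
    converged: bool
    at_bound: tuple[str, ...] = ()

    @property
    def k_as(self) -> float:
        return self.params.k_as

    @property
    def k_as_se(self) -> float:
        return self.se.get("k_as", math.nan)

    @property
    def kd_nM(self) -> float:
        return self.params.kd_nM

    @property
    def kd_se_nM(self) -> float:
        """SE of K_D propagated from K_as: SE_KD = SE_K / K^2 (unit-converted)."""
        return 1000.0 * self.k_as_se / self.k_as**2


_DEFAULT_K_STARTS = np.logspace(-3, 3, 12)  # 1/uM


def _residuals(p: lmfit.Parameters, L, F, p_scale, w):
    bp = BindingModelParams(
        k_as=p["k_as"].value,
        p_act=p["p_act"].value,
        f0=p["f0"].value,
        delta_phi=p["delta_phi"].value,
        phi_free=p["phi_free"].value,
    )
    return (model_fluorescence(L, bp, p_act=bp.p_act * p_scale) - F) * w


def fit_titration(
    curve: TitrationCurve,
    *,
    fix: dict[str, float] | None = None,
    per_point_protein: bool = True,
    weights: str | np.ndarray | None = None,
    k_starts=None,
    p_act_bounds=(0.2, 1.5),
) -> BindingFitResult:
    """Fit the quenching model to one corrected titration curve.

    Free parameters default to {k_as, p_act, f0, delta_phi, phi_free}; any can
    be fixed by name via ``fix``.  ``p_act`` is the pre-titration active
    protein concentration and is bounded to ``p_act_bounds`` times the nominal
    value to keep it from exchanging with ``delta_phi``; when
    ``per_point_protein`` is true the fit applies the known dilution profile
    so the protein term follows P_i = p_act * V0/V_i.

    By default the plain sum of squared residuals is minimized;
    ``weights="relative"`` weights residuals by 1/F (maximum likelihood when
    photometric noise is proportional to the signal), or pass an explicit
    per-point weight array.

    The optimisation is multi-started over a log-spaced grid of ``k_as``
    values (best SSR wins, ties to the smaller ``k_as``).  Standard errors
    come from the residual-variance-scaled inverse curvature at the optimum.
    """
    if len(curve) < 6:
        raise ValueError("need at least 6 titration points")
    fix = dict(fix or {})
    L = curve.ligand_uM
    F = curve.f_corrected
    p_nominal = float(curve.protein_uM[0])
    p_scale = curve.protein_uM / p_nominal if per_point_protein else np.ones_like(L)
    if weights is None:
        w = np.ones_like(F)
    elif isinstance(weights, str):
        if weights != "relative":
            raise ValueError(f"unknown weighting scheme {weights!r}")
        w = 1.0 / np.clip(np.abs(F), 1e-12 * np.max(np.abs(F)), None)
    else:
        w = np.asarray(weights, float)

    f0_guess = float(F[0])
    dphi_guess = max((f0_guess - float(F[-1])) / max(p_nominal, 1e-12), 1e-6)

    best = None
    k_grid = _DEFAULT_K_STARTS if k_starts is None else np.asarray(k_starts, float)
    if "k_as" in fix:
        k_grid = np.array([fix["k_as"]])
    for k0 in k_grid:
        pars = lmfit.Parameters()
        pars.add("k_as", value=float(k0), min=1e-9)
        pars.add("p_act", value=p_nominal,
                 min=p_act_bounds[0] * p_nominal, max=p_act_bounds[1] * p_nominal)
        pars.add("f0", value=f0_guess)
        pars.add("delta_phi", value=dphi_guess, min=0.0)
        pars.add("phi_free", value=0.0, min=0.0)
        for name, val in fix.items():
            pars[name].set(value=float(val), vary=False, min=-np.inf, max=np.inf)
        try:
            res = lmfit.minimize(
                _residuals, pars, args=(L, F, p_scale, w),
                method="least_squares", xtol=1e-10, ftol=1e-10, gtol=1e-10,
            )
        except Exception:
            continue
        ssr = float(np.sum(np.asarray(res.residual) ** 2))
        if best is None or ssr < best[0].chisqr - 1e-12 or (
            abs(ssr - best[0].chisqr) <= 1e-12
            and res.params["k_as"].value < best[0].params["k_as"].value
        ):
            best = (res, ssr)
    if best is None:
        raise RuntimeError("titration fit failed from every start")
    res, ssr = best

    fitted = BindingModelParams(
        k_as=res.params["k_as"].value,
        p_act=res.params["p_act"].value,
        f0=res.params["f0"].value,
        delta_phi=res.params["delta_phi"].value,
        phi_free=res.params["phi_free"].value,
    )
    se = {
        n: (float(res.params[n].stderr) if res.params[n].stderr is not None else math.nan)
        for n in res.params if res.params[n].vary
    }
    at_bound = []
    for n in ("p_act", "delta_phi", "phi_free"):
        p = res.params[n]
        if p.vary and p.min > -np.inf and np.isfinite(p.max):
            span = p.max - p.min
            if min(p.value - p.min, p.max - p.value) < 1e-6 * span:
                at_bound.append(n)
    if at_bound:
        warnings.warn(f"fitted parameter(s) at bound: {at_bound}", stacklevel=2)
    return BindingFitResult(
        params=fitted, se=se, ssr=ssr, n_points=len(curve),
        converged=bool(res.success), at_bound=tuple(at_bound),
    )


@dataclass(frozen=True)
class PooledBinding:
    """Inverse-variance pooled association/dissociation constants."""

    k_as: float
    k_as_se: float
    kd_nM: float
    kd_se_nM: float
    n_replicates: int
    weighted: bool = True


def pool_replicates(fits: list[BindingFitResult]) -> PooledBinding:
    """Pool replicate fits into a final K_as +/- SE by inverse-variance weights.

    w_i = 1/SE_i^2; pooled K = sum(w K)/sum(w), SE = sqrt(1/sum(w)).  Fits
    that did not converge or lack a finite SE are dropped; if no usable SEs
    remain, falls back to the unweighted mean (flagged via ``weighted=False``).
    The pooled K_as is converted to K_D = 1/K_as with SE_KD = SE_K / K^2.
    """
    usable = [f for f in fits if f.converged]
    if not usable:
        raise ValueError("no converged fits to pool")
    k = np.array([f.k_as for f in usable])
    se = np.array([f.k_as_se for f in usable])
    weighted = bool(np.all(np.isfinite(se)) and np.all(se > 0))
    if weighted:
        w = 1.0 / se**2
        k_pool = float(np.sum(w * k) / np.sum(w))
        se_pool = float(np.sqrt(1.0 / np.sum(w)))
    else:
        warnings.warn("missing or zero SEs; falling back to unweighted mean",
                      stacklevel=2)
        k_pool = float(np.mean(k))
        se_pool = float(np.std(k, ddof=1) / np.sqrt(len(k))) if len(k) > 1 else math.nan
    return PooledBinding(
        k_as=k_pool,
        k_as_se=se_pool,
        kd_nM=1000.0 / k_pool,
        kd_se_nM=1000.0 * se_pool / k_pool**2,
        n_replicates=len(usable),
        weighted=weighted,
    )
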