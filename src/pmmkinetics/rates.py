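"""Rate-constant theory: barrier-crossing, diffusion-limited association,
and the kinetic scheme combining them.

The slow chemical step is treated with transition-state flux theory on the
Landau free-energy profile A(ξ):

    KR = exp(−β ΔA‡) · ⟨v⟩ / (2 ∫_{ξm}^{ξTS} exp(−β ΔA(ξ)) dξ)

with ⟨v⟩ the equilibrium mean speed along the coordinate (the factor 1/2
counts only the outward-moving half of the transition-state population).
The tiny transition-state width δ used in intermediate definitions cancels
exactly between the partition-function and flux expressions and therefore
never appears as a parameter.

Association of the two reactants is diffusion-limited (Smoluchowski):
kA = 4π (D1 + D2) r0 NA, with r0 the encounter-complex radius.  The full
scheme

    S + OH⁻  ⇌(kA / k2)  CNR  ⇌(k−1 / k1)  CR  →(KR)  P

(CNR/CR the non-reactive and reactive encounter complexes; k1 the CR→CNR
rate, k−1 the CNR→CR rate, k2 the CNR dissociation rate) yields, under the
steady-state approximation for both complexes, the overall bimolecular rate

    kH = KR·kA·k−1 / ((k2 + k−1)(k1 + KR) − k1·k−1)  ≅  kA·k−1·KR/(k1·k2)

where the approximation uses KR ≪ k1.  An ODE integrator validates the
steady-state algebra numerically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .constants import (
    AVOGADRO,
    KB_KCAL,
    NM3_TO_L,
    PS_TO_S,
    thermal_energy_amu_nm2_ps2,
)
from .free_energy import FreeEnergyProfile, locate_barrier

__all__ = [
    "ThermoParams",
    "SpeedModel",
    "RateConstants",
    "OdeValidation",
    "mean_traversing_speed",
    "traversing_speed_from_trajectory",
    "reactant_integral",
    "transition_rate_KR",
    "transition_rate_KR_via_delta",
    "smoluchowski_kA",
    "einstein_diffusion",
    "hydrolysis_rate_kH",
    "scheme_ode_validate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThermoParams:
    """Temperature and derived inverse thermal energy."""

    temperature: float = 300.0  # K
    kB: float = KB_KCAL  # kcal/(mol·K)

    @property
    def beta(self) -> float:
        """1/(kB T) in mol/kcal."""
        return 1.0 / (self.kB * self.temperature)


@dataclass(frozen=True)
class SpeedModel:
    """Mean transition-state traversing speed and the mass behind it."""

    mu: float  # effective mass along ξ, amu
    mean_speed: float  # ⟨|dξ/dt|⟩, nm/ps

    def __post_init__(self):
        if self.mean_speed <= 0:
            raise ValueError("mean traversing speed must be positive")


@dataclass
class RateConstants:
    """The full rate-constant set of the association/reaction scheme.

    Units: kA in ps⁻¹M⁻¹; kD, k1, k_minus1, k2 in ps⁻¹; KR and kH in s⁻¹
    (kH per molar); D in nm²/ps; r0 in nm.  ``provenance`` records whether
    each entry was computed by the pipeline or supplied by the user.
    """

    kA: float | None = None
    kD: float | None = None
    k1: float | None = None
    k_minus1: float | None = None
    k2: float | None = None
    chi_eq: float | None = None
    KR: float | None = None
    kH: float | None = None
    kH_approx: float | None = None
    r0: float | None = None
    D_substrate: float | None = None
    D_nucleophile: float | None = None
    provenance: dict = field(default_factory=dict)

    UNITS = {
        "kA": "ps^-1 M^-1", "kD": "ps^-1", "k1": "ps^-1", "k_minus1": "ps^-1",
        "k2": "ps^-1", "chi_eq": "1", "KR": "s^-1", "kH": "s^-1 M^-1",
        "kH_approx": "s^-1 M^-1", "r0": "nm", "D_substrate": "nm^2 ps^-1",
        "D_nucleophile": "nm^2 ps^-1",
    }

    def __post_init__(self):
        for name in self.UNITS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.chi_eq is not None and not 0 <= self.chi_eq <= 1:
            raise ValueError(f"chi_eq must lie in [0, 1], got {self.chi_eq}")

    def as_dict(self) -> dict:
        out = {}
        for name, unit in self.UNITS.items():
            out[name] = {
                "value": getattr(self, name),
                "unit": unit,
                "provenance": self.provenance.get(name, "computed"),
            }
        return out


def mean_traversing_speed(thermo: ThermoParams, mu: float) -> float:
    """1-D Maxwell–Boltzmann mean speed √(2 kB T / (π μ)) in nm/ps.

    ``mu`` is the effective (reduced) mass along the reaction coordinate in
    amu.  Scales as T^½ and μ^−½.
    """
    if mu <= 0:
        raise ValueError(f"effective mass must be positive, got {mu}")
    kbt = thermal_energy_amu_nm2_ps2(thermo.temperature)  # amu·nm²/ps²
    return math.sqrt(2.0 * kbt / (math.pi * mu))


def traversing_speed_from_trajectory(times: Sequence[float], xi: Sequence[float]) -> float:
    """Direct estimator ⟨|Δξ/Δt|⟩ from a sampled ξ(t) trajectory (nm/ps)."""
    t = np.asarray(times, dtype=float)
    x = np.asarray(xi, dtype=float)
    if t.size != x.size or t.size < 2:
        raise ValueError("need matching time/xi series with at least two points")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.mean(np.abs(np.diff(x) / dt)))


def reactant_integral(
    profile: FreeEnergyProfile,
    thermo: ThermoParams,
    xi_m: float | None = None,
    xi_TS: float | None = None,
) -> float:
    """Configurational integral of the reactant well, ∫ exp(−β ΔA) dξ (nm).

    Trapezoidal quadrature on the profile grid over [ξm, ξTS]; defaults to
    the profile's stored bounds.
    """
    xi_m = profile.xi_m if xi_m is None else xi_m
    xi_TS = profile.xi_TS if xi_TS is None else xi_TS
    if xi_TS is None:
        raise ValueError("profile has no located transition state; run locate_barrier")
    mask = (profile.xi >= xi_m - 1e-12) & (profile.xi <= xi_TS + 1e-12)
    if mask.sum() < 2:
        raise ValueError("empty integration range [xi_m, xi_TS]")
    x = profile.xi[mask]
    integrand = np.exp(-thermo.beta * profile.delta_a[mask])
    return float(np.trapezoid(integrand, x))


def transition_rate_KR(
    profile: FreeEnergyProfile, thermo: ThermoParams, speed: SpeedModel
) -> float:
    """Barrier-crossing rate constant KR (s⁻¹) from the free-energy profile.

    KR = exp(−β ΔA‡) · ⟨v⟩ / (2 QR) with QR the reactant integral; the
    result is converted from ps⁻¹ to s⁻¹.
    """
    if profile.barrier is None:
        xi_r, xi_ts, barrier = locate_barrier(profile)
        profile.xi_R, profile.xi_TS, profile.barrier = xi_r, xi_ts, barrier
    q_r = reactant_integral(profile, thermo)
    kr_ps = math.exp(-thermo.beta * profile.barrier) * speed.mean_speed / (2.0 * q_r)
    logger.info(
        "KR: barrier=%.3f kcal/mol, QR=%.5g nm, <v>=%.4g nm/ps -> %.4g s^-1",
        profile.barrier, q_r, speed.mean_speed, kr_ps / PS_TO_S,
    )
    return kr_ps / PS_TO_S


def transition_rate_KR_via_delta(
    profile: FreeEnergyProfile,
    thermo: ThermoParams,
    speed: SpeedModel,
    delta: float,
) -> float:
    """KR through the explicit finite-width route (s⁻¹).

    Uses QTS ≅ exp(−β ΔA‡)·δ and the flux rate k = ⟨v⟩/δ, so the
    transition-state width δ cancels identically; exposed to make that
    cancellation checkable rather than assumed.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if profile.barrier is None:
        raise ValueError("profile has no located barrier")
    q_r = reactant_integral(profile, thermo)
    q_ts = math.exp(-thermo.beta * profile.barrier) * delta
    k_flux = speed.mean_speed / delta
    return (q_ts / q_r) * (k_flux / 2.0) / PS_TO_S


def smoluchowski_kA(D_sum: float, r0: float) -> float:
    """Diffusion-limited association constant kA = 4π D r0 NA (ps⁻¹M⁻¹).

    ``D_sum`` is the sum of the two free diffusion coefficients (nm²/ps),
    ``r0`` the encounter radius (nm); the Avogadro factor folds nm³ into
    litres, i.e. kA = 4π·D_sum·r0·0.60221… in ps⁻¹M⁻¹.
    """
    if r0 <= 0:
        raise ValueError(f"encounter radius must be positive, got {r0}")
    if D_sum < 0:
        raise ValueError("diffusion coefficient sum must be non-negative")
    return 4.0 * math.pi * D_sum * r0 * AVOGADRO * NM3_TO_L


def einstein_diffusion(
    times: Sequence[float],
    msd: Sequence[float],
    fit_window: tuple[float, float] = (0.1, 0.5),
) -> float:
    """Diffusion coefficient from a mean-square-displacement track (nm²/ps).

    D = slope/6 of the least-squares line through MSD(t), fitted over the
    ``fit_window`` fraction of the total time span (default 10–50%, skipping
    the ballistic start and the poorly averaged tail).  The intercept is
    free, so a constant MSD offset does not bias D.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(msd, dtype=float)
    if t.size != y.size or t.size < 10:
        raise ValueError("need at least 10 matching (t, MSD) points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    lo = t[0] + fit_window[0] * (t[-1] - t[0])
    hi = t[0] + fit_window[1] * (t[-1] - t[0])
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 2:
        raise ValueError("fit window selects fewer than two points")
    slope, _ = np.polyfit(t[mask], y[mask], 1)
    return float(slope) / 6.0


def hydrolysis_rate_kH(rates: RateConstants) -> tuple[float, float]:
    """Overall bimolecular rate constant (full, approximate) in s⁻¹M⁻¹.

    Full steady-state form: kH = KR·kA·k−1 / ((k2+k−1)(k1+KR) − k1·k−1);
    approximate form (KR ≪ k1): kH ≅ kA·k−1·KR / (k1·k2).  KR is taken in
    s⁻¹ and the ps-based constants are harmonized internally.
    """
    for name in ("kA", "k1", "k_minus1", "k2", "KR"):
        v = getattr(rates, name)
        if v is None or v <= 0:
            raise ValueError(f"hydrolysis_rate_kH requires positive {name}")
    kr_ps = rates.KR * PS_TO_S  # s⁻¹ -> ps⁻¹
    k1, km1, k2, ka = rates.k1, rates.k_minus1, rates.k2, rates.kA
    denom = (k2 + km1) * (k1 + kr_ps) - k1 * km1
    if denom <= 0:
        raise ValueError("degenerate scheme: non-positive steady-state denominator")
    full = kr_ps * ka * km1 / denom / PS_TO_S
    approx = ka * km1 * kr_ps / (k1 * k2) / PS_TO_S
    return full, approx


@dataclass
class OdeValidation:
    """Numerical cross-check of the steady-state rate algebra."""

    effective_rate: float  # fitted pseudo-first-order decay of substrate, ps⁻¹
    predicted_rate: float  # kH·[HO⁻] from the algebraic formula, ps⁻¹
    conservation_error: float  # max relative drift of total substrate material
    times: np.ndarray
    concentrations: np.ndarray  # rows: S, CNR, CR, P


def scheme_ode_validate(
    rates: RateConstants,
    substrate0: float = 1e-3,
    hydroxide: float = 1e-3,
    horizon: float | None = None,
    transient_fraction: float = 0.2,
    n_eval: int = 400,
) -> OdeValidation:
    """Integrate the full scheme and fit the substrate's exponential decay.

    The hydroxide concentration is held fixed (pseudo-first-order excess).
    Species: free substrate S, non-reactive complex CNR, reactive complex
    CR, product P.  After discarding an equilibration transient, a single
    exponential is fitted to the free-substrate decay; the fitted rate is
    compared against kH·[HO⁻].  The steady-state algebra further assumes
    the complexed population stays small next to S, which holds in the
    dilute regime kA·[HO⁻] ≪ k2.
    """
    for name in ("kA", "k1", "k_minus1", "k2", "KR"):
        if getattr(rates, name) is None:
            raise ValueError(f"scheme_ode_validate requires {name}")
    ka, k1, km1, k2 = rates.kA, rates.k1, rates.k_minus1, rates.k2
    kr = rates.KR * PS_TO_S  # ps⁻¹
    kh_full, _ = (
        hydrolysis_rate_kH(rates) if kr > 0 else (0.0, 0.0)
    )
    predicted = kh_full * PS_TO_S * hydroxide  # ps⁻¹

    if horizon is None:
        horizon = 3.0 / predicted if predicted > 0 else 1e4 / max(k2, km1, 1e-12)

    def rhs(_t, y):
        s, cnr, cr, _p = y
        assoc = ka * s * hydroxide
        return [
            -assoc + k2 * cnr,
            assoc - (k2 + km1) * cnr + k1 * cr,
            km1 * cnr - (k1 + kr) * cr,
            kr * cr,
        ]

    t_eval = np.linspace(0.0, horizon, n_eval)
    sol = solve_ivp(
        rhs, (0.0, horizon), [substrate0, 0.0, 0.0, 0.0],
        method="LSODA", t_eval=t_eval, rtol=1e-10, atol=substrate0 * 1e-14,
    )
    if not sol.success:
        raise RuntimeError(
            f"stiff integration failed ({sol.message}); retry with a shorter "
            "horizon or smaller step via n_eval"
        )
    y = sol.y
    total = y[:3].sum(axis=0) + y[3]
    conservation = float(np.max(np.abs(total - substrate0)) / substrate0)

    mask = sol.t >= transient_fraction * horizon
    s = y[0, mask]
    if np.any(s <= 0) or s[0] <= s[-1]:
        effective = 0.0
    else:
        slope, _ = np.polyfit(sol.t[mask], np.log(s), 1)
        effective = float(-slope)
    return OdeValidation(
        effective_rate=effective,
        predicted_rate=predicted,
        conservation_error=conservation,
        times=sol.t,
        concentrations=y,
    )
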