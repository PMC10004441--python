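"""Model/Results front end tying the pipeline stages together.

``ReactionKineticsModel`` holds the raw evidence — windowed perturbed
energies, dissociation trajectory ensembles, the equilibrium distance
record, diffusion data — plus the physical parameters (temperature,
effective mass, complex radii).  ``fit()`` runs the full estimation chain
and returns a ``ReactionKineticsResults`` with the free-energy profile,
every rate constant of the association/reaction scheme, bootstrap
confidence intervals for the fitted decay rates, and a ``summary()`` table.

A model can be built directly from arrays, from a validated
``PipelineConfig`` (``from_config``), or entirely from the synthetic
generators (``from_synthetic``) for end-to-end demonstrations with known
ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import io as pio
from .config import PipelineConfig
from .free_energy import (
    FreeEnergyProfile,
    Window,
    average_profiles,
    reconstruct_profile,
)
from .kinetics import (
    DistanceTrajectory,
    SurvivalCurve,
    derive_secondary_rates,
    detect_r0_quadratic,
    equilibrium_nonreactive_fraction,
    fit_first_order_decay,
    survival_from_ensemble,
)
from .rates import (
    RateConstants,
    SpeedModel,
    ThermoParams,
    einstein_diffusion,
    hydrolysis_rate_kH,
    mean_traversing_speed,
    scheme_ode_validate,
    smoluchowski_kA,
    transition_rate_KR,
)
from . import synthetic as syn

__all__ = ["ReactionKineticsModel", "ReactionKineticsResults"]

logger = logging.getLogger(__name__)


@dataclass
class ReactionKineticsResults:
    """Fitted rate constants, profiles and diagnostics."""

    rates: RateConstants
    thermo: ThermoParams
    speed: SpeedModel | None = None
    profile: FreeEnergyProfile | None = None
    profile_forward: FreeEnergyProfile | None = None
    profile_backward: FreeEnergyProfile | None = None
    survival_overall: SurvivalCurve | None = None
    survival_reactive: SurvivalCurve | None = None
    kD_ci: tuple | None = None
    k1_ci: tuple | None = None
    ode_validation: object | None = None
    warnings: list = field(default_factory=list)

    @property
    def barrier(self) -> float | None:
        return None if self.profile is None else self.profile.barrier

    def summary(self) -> str:
        """Human-readable results table."""
        lines = [
            "Bimolecular reaction kinetics — fitted rate constants",
            "=" * 58,
            f"temperature: {self.thermo.temperature:.1f} K",
        ]
        if self.speed is not None:
            lines.append(
                f"mean traversing speed <v>: {self.speed.mean_speed:.4f} nm/ps "
                f"(mu = {self.speed.mu:g} amu)"
            )
        if self.profile is not None and self.profile.barrier is not None:
            lines += [
                f"free-energy barrier:  {self.profile.barrier:.2f} kcal/mol "
                f"(xi_R = {self.profile.xi_R:.3f} nm, xi_TS = {self.profile.xi_TS:.3f} nm)",
            ]
        lines.append("-" * 58)
        lines.append(f"{'constant':<12}{'value':>14}  unit")
        for name, unit in RateConstants.UNITS.items():
            v = getattr(self.rates, name)
            shown = "null" if v is None else f"{v:.4g}"
            ci = ""
            if name == "kD" and self.kD_ci:
                ci = f"  (95% CI {self.kD_ci[0]:.4g}–{self.kD_ci[1]:.4g})"
            if name == "k1" and self.k1_ci:
                ci = f"  (95% CI {self.k1_ci[0]:.4g}–{self.k1_ci[1]:.4g})"
            lines.append(f"{name:<12}{shown:>14}  {unit}{ci}")
        if self.ode_validation is not None:
            ov = self.ode_validation
            lines += [
                "-" * 58,
                f"ODE cross-check: effective rate {ov.effective_rate:.4g} ps^-1 "
                f"vs steady-state {ov.predicted_rate:.4g} ps^-1",
            ]
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def plot_profile(self, ax=None):
        """Free-energy profile with the located minimum and barrier."""
        import matplotlib.pyplot as plt

        if self.profile is None:
            raise ValueError("no free-energy profile was fitted")
        if ax is None:
            _, ax = plt.subplots()
        for p, style in (
            (self.profile_forward, "C0:"),
            (self.profile_backward, "C1:"),
            (self.profile, "k-"),
        ):
            if p is not None:
                ax.plot(p.xi, p.delta_a, style, label=p.direction)
        if self.profile.xi_TS is not None:
            ax.axvline(self.profile.xi_TS, color="grey", lw=0.5)
        ax.set_xlabel(r"$\xi$ (nm)")
        ax.set_ylabel(r"$\Delta A$ (kcal/mol)")
        ax.legend()
        return ax

    def plot_survival(self, ax=None):
        """Survival curves of the dissociation ensembles (log scale)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for curve, label in (
            (self.survival_overall, "overall complex"),
            (self.survival_reactive, "reactive complex"),
        ):
            if curve is not None:
                ax.semilogy(curve.times, np.maximum(curve.fraction, 1e-3), label=label)
        ax.set_xlabel("t (ps)")
        ax.set_ylabel("surviving fraction")
        ax.legend()
        return ax


@dataclass
class ReactionKineticsModel:
    """Evidence and parameters for the full rate-constant estimation."""

    windows: Sequence[Window] | None = None
    overall_escape: Sequence[DistanceTrajectory] | None = None
    reactive_escape: Sequence[DistanceTrajectory] | None = None
    equilibrium_distances: np.ndarray | None = None
    msd: tuple | None = None  # (times, ensemble-mean MSD) for the substrate
    temperature: float = 300.0
    effective_mass: float = 17.0  # amu
    r_reactive: float = 0.6  # nm
    r0: float = 1.2  # nm
    detect_r0: bool = False
    d_substrate: float | None = None  # nm²/ps
    d_nucleophile: float | None = None
    survival_mode: str = "first_passage"
    n_bootstrap: int = 1000
    seed: int = 0
    overrides: dict = field(default_factory=dict)
    hydroxide_M: float = 1e-3
    ode_check: bool = False

    # ------------------------------------------------------------------ build
    @classmethod
    def from_synthetic(
        cls,
        seed: int = 0,
        barrier: float = 38.8,
        frames: int = 20000,
        kD_true: float = 0.0056,
        k1_true: float = 0.030,
        **kwargs,
    ) -> "ReactionKineticsModel":
        """All-synthetic model at the default study conditions."""
        target = syn.default_target_profile(barrier=barrier)
        wspec = syn.WindowGeneratorSpec.from_profile(target, frames=frames)
        windows, _ = syn.gen_windows(wspec, seed=seed)
        overall = syn.gen_escape_ensemble(
            syn.EscapeGeneratorSpec(rate=kD_true), seed=seed + 1
        )
        reactive = syn.gen_escape_ensemble(
            syn.EscapeGeneratorSpec(
                rate=k1_true, cutoff=0.6, bound_range=(0.45, 0.58),
                escaped_range=(0.62, 1.15),
            ),
            seed=seed + 2,
        )
        eq = syn.gen_pair_equilibrium(
            syn.PairEquilibriumSpec(n_steps=400000), seed=seed + 3
        )
        return cls(
            windows=windows,
            overall_escape=overall,
            reactive_escape=reactive,
            equilibrium_distances=eq.distances,
            d_substrate=1.0e-3,
            d_nucleophile=5.27e-3,
            seed=seed,
            **kwargs,
        )

    @classmethod
    def from_config(cls, config: PipelineConfig, seed: int | None = None) -> "ReactionKineticsModel":
        seed = config.seed if seed is None else seed
        windows = None
        if config.free_energy is not None:
            fe = config.free_energy
            if fe.window_files:
                windows = [
                    pio.read_window_csv(p, index=i) for i, p in enumerate(fe.window_files)
                ]
            elif fe.synthetic is not None:
                s = fe.synthetic
                target = syn.default_target_profile(
                    barrier=s.barrier, xi_start=s.xi_start, xi_end=s.xi_end,
                    n_points=s.n_points, xi_R=s.xi_R, xi_TS=s.xi_TS,
                )
                wspec = syn.WindowGeneratorSpec.from_profile(
                    target, n_windows=s.n_windows, frames=s.frames,
                    temperature=config.temperature, sigma_slope=s.sigma_slope,
                )
                windows, _ = syn.gen_windows(wspec, seed=seed)
        overall = reactive = None
        eq_dist = None
        cc = config.complex
        if cc is not None:
            if cc.trajectory_files:
                overall = [pio.read_distance_csv(p) for p in cc.trajectory_files]
            elif cc.wide_file:
                overall = pio.read_distance_wide_csv(cc.wide_file)
            elif cc.synthetic_overall is not None:
                so = cc.synthetic_overall
                overall = syn.gen_escape_ensemble(
                    syn.EscapeGeneratorSpec(
                        n_trajectories=so.n_trajectories, length=so.length,
                        dt=so.dt, rate=so.rate, cutoff=cc.r0,
                        bound_range=(0.2, cc.r0 - 0.05),
                        escaped_range=(cc.r0 + 0.05, cc.r0 + 1.8),
                    ),
                    seed=seed + 1,
                )
            if cc.reactive_trajectory_files:
                reactive = [pio.read_distance_csv(p) for p in cc.reactive_trajectory_files]
            elif cc.synthetic_reactive is not None:
                sr = cc.synthetic_reactive
                reactive = syn.gen_escape_ensemble(
                    syn.EscapeGeneratorSpec(
                        n_trajectories=sr.n_trajectories, length=sr.length,
                        dt=sr.dt, rate=sr.rate, cutoff=cc.r_reactive,
                        bound_range=(0.45, cc.r_reactive - 0.02),
                        escaped_range=(cc.r_reactive + 0.02, cc.r0 - 0.05),
                    ),
                    seed=seed + 2,
                )
            if cc.equilibrium_file:
                eq_dist = pio.read_distance_csv(cc.equilibrium_file).distances
            elif cc.synthetic_equilibrium is not None:
                se = cc.synthetic_equilibrium
                eq = syn.gen_pair_equilibrium(
                    syn.PairEquilibriumSpec(
                        well_depth=se.well_depth, well_edge=se.well_edge,
                        outer_radius=se.outer_radius, diffusion=se.diffusion,
                        dt=se.dt, n_steps=se.n_steps,
                        temperature=config.temperature,
                    ),
                    seed=seed + 3,
                )
                eq_dist = eq.distances
        msd = None
        dc = config.diffusion
        if dc.msd_file:
            msd = pio.read_msd_csv(dc.msd_file)
        elif dc.synthetic_msd:
            t, sq = syn.gen_msd_tracks(
                D=dc.d_substrate or 1e-3, step=dc.msd_step,
                n_steps=dc.msd_n_steps, n_tracks=dc.msd_n_tracks, seed=seed + 4,
            )
            msd = (t, sq.mean(axis=0))
        return cls(
            windows=windows,
            overall_escape=overall,
            reactive_escape=reactive,
            equilibrium_distances=eq_dist,
            msd=msd,
            temperature=config.temperature,
            effective_mass=config.rates.effective_mass_amu,
            r_reactive=cc.r_reactive if cc else 0.6,
            r0=cc.r0 if cc else 1.2,
            detect_r0=cc.detect_r0 if cc else False,
            d_substrate=dc.d_substrate,
            d_nucleophile=dc.d_nucleophile,
            survival_mode=cc.survival_mode if cc else "first_passage",
            n_bootstrap=cc.n_bootstrap if cc else 1000,
            seed=seed,
            overrides=dict(config.rates.overrides),
            hydroxide_M=config.rates.hydroxide_M,
            ode_check=config.rates.ode_check,
        )

    # -------------------------------------------------------------------- fit
    def fit(self) -> ReactionKineticsResults:
        """Run every estimation stage the available evidence supports."""
        thermo = ThermoParams(temperature=self.temperature)
        rates = RateConstants()
        warnings: list[str] = []
        res = ReactionKineticsResults(rates=rates, thermo=thermo, warnings=warnings)

        # stage 1: free-energy profile and barrier-crossing rate
        if self.windows is not None:
            fwd = reconstruct_profile(self.windows, self.temperature, "forward")
            bwd = reconstruct_profile(self.windows, self.temperature, "backward")
            avg = average_profiles(fwd, bwd)
            res.profile_forward, res.profile_backward, res.profile = fwd, bwd, avg
            speed = SpeedModel(
                mu=self.effective_mass,
                mean_speed=mean_traversing_speed(thermo, self.effective_mass),
            )
            res.speed = speed
            if avg.barrier is not None:
                rates.KR = transition_rate_KR(avg, thermo, speed)
                logger.info("barrier %.2f kcal/mol -> KR = %.4g s^-1", avg.barrier, rates.KR)
            else:
                warnings.append("no barrier located on the averaged profile")

        # stage 2: equilibrium distance record -> r0 and chi_eq
        r0 = self.r0
        if self.equilibrium_distances is not None:
            if self.detect_r0:
                r0, _c = detect_r0_quadratic(self.equilibrium_distances)
                logger.info("detected complex radius r0 = %.3f nm", r0)
            rates.chi_eq = equilibrium_nonreactive_fraction(
                self.equilibrium_distances, self.r_reactive, r0
            )
            logger.info("equilibrium non-reactive fraction chi_eq = %.3f", rates.chi_eq)
        rates.r0 = r0

        # stage 3: diffusion -> association constant
        d_sub = self.d_substrate
        if self.msd is not None:
            d_sub = einstein_diffusion(*self.msd)
            logger.info("Einstein-fit substrate D = %.4g nm^2/ps", d_sub)
        rates.D_substrate, rates.D_nucleophile = d_sub, self.d_nucleophile
        if d_sub is not None and self.d_nucleophile is not None:
            rates.kA = smoluchowski_kA(d_sub + self.d_nucleophile, r0)
            logger.info("Smoluchowski kA = %.4g ps^-1 M^-1", rates.kA)

        # stage 4: dissociation ensembles -> kD and k1
        if self.overall_escape is not None:
            res.survival_overall = survival_from_ensemble(
                self.overall_escape, r0, mode=self.survival_mode
            )
            rates.kD, res.kD_ci = fit_first_order_decay(
                res.survival_overall, n_bootstrap=self.n_bootstrap, seed=self.seed
            )
            logger.info("overall-complex escape rate kD = %.4g ps^-1", rates.kD)
        if self.reactive_escape is not None:
            res.survival_reactive = survival_from_ensemble(
                self.reactive_escape, self.r_reactive, mode=self.survival_mode
            )
            rates.k1, res.k1_ci = fit_first_order_decay(
                res.survival_reactive, n_bootstrap=self.n_bootstrap, seed=self.seed + 1
            )
            logger.info("reactive-complex exit rate k1 = %.4g ps^-1", rates.k1)

        # user-supplied constants take precedence, tagged as such
        for name, value in self.overrides.items():
            setattr(rates, name, value)
            rates.provenance[name] = "supplied"

        # stage 5: close the scheme
        if rates.k1 is not None and rates.kD is not None and rates.chi_eq is not None:
            if "k_minus1" not in self.overrides or "k2" not in self.overrides:
                km1, k2 = derive_secondary_rates(rates.k1, rates.kD, rates.chi_eq)
                rates.k_minus1 = self.overrides.get("k_minus1", km1)
                rates.k2 = self.overrides.get("k2", k2)
        for name, value in self.overrides.items():
            setattr(rates, name, value)
            rates.provenance[name] = "supplied"

        missing = [
            n for n in ("kA", "k1", "k_minus1", "k2", "KR")
            if getattr(rates, n) is None
        ]
        if missing:
            warnings.append(
                f"cannot evaluate the overall rate constant: missing {missing}"
            )
            logger.warning("partial output: missing %s", missing)
        else:
            rates.kH, rates.kH_approx = hydrolysis_rate_kH(rates)
            logger.info(
                "overall rate constant kH = %.4g s^-1 M^-1 (approx %.4g)",
                rates.kH, rates.kH_approx,
            )
            if self.ode_check:
                res.ode_validation = scheme_ode_validate(
                    rates, hydroxide=self.hydroxide_M
                )
        return res
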