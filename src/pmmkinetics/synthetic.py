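"""Synthetic inputs with known ground truth for every pipeline stage.

Real inputs to this pipeline are electronic-structure reaction profiles and
MD trajectories.  The generators here emulate only the *statistical
structure* the estimators rely on — near-Gaussian perturbed-energy
fluctuations within each sampling window, exponential first-passage escape
from the encounter complex, an equilibrium pair-distance density that is a
bound population on top of a free r² tail, and free 3-D Brownian motion —
and each one carries its analytic oracle (closed-form free-energy profile,
exponential law, stationary density, MSD slope), so recovery tests compare
estimates against exact ground truth.  Every generator is a pure function
of its spec and seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .constants import beta as beta_of
from .free_energy import FreeEnergyProfile, Window, locate_barrier
from .kinetics import DistanceTrajectory
from .pmm import EnvironmentSnapshot

__all__ = [
    "WindowSpec",
    "WindowGeneratorSpec",
    "EscapeGeneratorSpec",
    "PairEquilibriumSpec",
    "default_target_profile",
    "gen_windows",
    "gen_escape_ensemble",
    "gen_pair_equilibrium",
    "gen_msd_tracks",
    "gen_point_charge_bath",
]

logger = logging.getLogger(__name__)

#: Default ΔU spread growth away from the window reference,
#: kcal·mol⁻¹ per nm of |ξ − ξref| (≈1.2 kcal/mol at a typical window edge,
#: matching near-Gaussian fluctuation widths of a few kcal/mol).
SIGMA_SLOPE_DEFAULT = 10.0


def default_target_profile(
    barrier: float = 38.8,
    xi_start: float = 0.0,
    xi_end: float = 0.5,
    n_points: int = 41,
    xi_R: float = 0.1,
    xi_TS: float = 0.45,
    well_stiffness: float = 500.0,
    post_ts_drop: float = 2.0,
) -> FreeEnergyProfile:
    """Analytic reaction free-energy profile: harmonic reactant well,
    smooth rise to an interior transition state, slight drop beyond it.

    The barrier (kcal/mol) is ΔA(ξTS) − ΔA(ξR) exactly; ξR and ξTS are
    placed on the grid.
    """
    xi = np.linspace(xi_start, xi_end, n_points)
    da = np.empty_like(xi)
    left = xi <= xi_R
    da[left] = 0.5 * well_stiffness * (xi[left] - xi_R) ** 2
    mid = (xi > xi_R) & (xi <= xi_TS)
    da[mid] = barrier * np.sin(0.5 * np.pi * (xi[mid] - xi_R) / (xi_TS - xi_R)) ** 2
    right = xi > xi_TS
    da[right] = barrier - post_ts_drop * (xi[right] - xi_TS) / max(xi_end - xi_TS, 1e-12)
    profile = FreeEnergyProfile(xi=xi, delta_a=da, direction="exact")
    profile.xi_R, profile.xi_TS, profile.barrier = locate_barrier(profile)
    return profile


@dataclass(frozen=True)
class WindowSpec:
    """Per-window generator parameters: ΔU mean/spread at each grid point."""

    xi: np.ndarray
    xi_ref: float
    means: np.ndarray  # kcal/mol, relative to the window reference
    sigmas: np.ndarray  # kcal/mol
    mixture_delta: float = 0.0  # ±shift of a symmetric two-Gaussian mixture

    def __post_init__(self):
        object.__setattr__(self, "xi", np.asarray(self.xi, dtype=float).ravel())
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float).ravel())
        object.__setattr__(self, "sigmas", np.asarray(self.sigmas, dtype=float).ravel())
        if not (self.xi.size == self.means.size == self.sigmas.size):
            raise ValueError("xi / means / sigmas must have equal length")
        if np.any(self.sigmas < 0):
            raise ValueError("sigmas must be non-negative")
        if np.any(np.diff(self.xi) <= 0):
            raise ValueError("window grid must be strictly increasing")

    def analytic_increment(self, i: int, temperature: float) -> float:
        """Exact ΔA(ξref → ξi) of the generating distribution.

        Gaussian: m − βσ²/2; symmetric two-Gaussian mixture with shift d
        adds −ln(cosh(βd))/β.
        """
        if self.xi[i] == self.xi_ref:
            return 0.0  # ΔU ≡ 0 at the reference by construction
        b = beta_of(temperature)
        out = self.means[i] - b * self.sigmas[i] ** 2 / 2.0
        if self.mixture_delta:
            out -= math.log(math.cosh(b * self.mixture_delta)) / b
        return float(out)


@dataclass(frozen=True)
class WindowGeneratorSpec:
    """Full windowed-sampling experiment: N windows, frames per window."""

    windows: tuple
    frames: int = 20000
    temperature: float = 300.0

    def __post_init__(self):
        object.__setattr__(self, "windows", tuple(self.windows))
        if self.frames < 1:
            raise ValueError("frames must be >= 1")
        refs = [w.xi_ref for w in self.windows]
        if np.any(np.diff(refs) <= 0):
            raise ValueError("window references must be strictly increasing")

    @classmethod
    def from_profile(
        cls,
        profile: FreeEnergyProfile,
        n_windows: int = 5,
        frames: int = 20000,
        temperature: float = 300.0,
        sigma_slope: float = SIGMA_SLOPE_DEFAULT,
        mixture_delta: float = 0.0,
    ) -> "WindowGeneratorSpec":
        """Windows whose analytic stitched profile equals ``profile`` exactly.

        References are spread evenly over the grid; each window's grid spans
        to both neighbouring references (so forward and backward passes each
        cover every sub-range).  Per-point means are back-computed from the
        target so the generating distribution's exact free-energy change
        from ξref to ξ equals the target difference.
        """
        if n_windows < 1:
            raise ValueError("need at least one window")
        xi, da = profile.xi, profile.delta_a
        ref_idx = np.unique(np.round(np.linspace(0, xi.size - 1, n_windows)).astype(int))
        if ref_idx.size != n_windows:
            raise ValueError("grid too coarse for the requested window count")
        b = beta_of(temperature)
        correction = math.log(math.cosh(b * mixture_delta)) / b if mixture_delta else 0.0
        specs = []
        for n, i_ref in enumerate(ref_idx):
            lo = ref_idx[n - 1] if n > 0 else 0
            hi = ref_idx[n + 1] if n < n_windows - 1 else xi.size - 1
            sel = np.arange(lo, hi + 1)
            w_xi = xi[sel]
            sigmas = sigma_slope * np.abs(w_xi - xi[i_ref])
            target = da[sel] - da[i_ref]
            means = target + b * sigmas**2 / 2.0 + correction
            # mixture correction does not apply where sigma-free ref point sits
            means[w_xi == xi[i_ref]] = 0.0
            sig = sigmas.copy()
            specs.append(
                WindowSpec(
                    xi=w_xi, xi_ref=float(xi[i_ref]), means=means, sigmas=sig,
                    mixture_delta=mixture_delta,
                )
            )
        return cls(windows=tuple(specs), frames=frames, temperature=temperature)

    def analytic_profile(self) -> FreeEnergyProfile:
        """Exact profile implied by the generating distributions.

        Chained forward over the windows (the exact increments make the
        backward chain identical), re-zeroed at the minimum.
        """
        values: dict[float, float] = {}
        offset = 0.0
        wins = self.windows
        for n, w in enumerate(wins):
            lo = -np.inf if n == 0 else w.xi_ref
            hi = np.inf if n == len(wins) - 1 else wins[n + 1].xi_ref
            for i, x in enumerate(w.xi):
                if (x <= hi) and (n == 0 or x > lo):
                    values[round(float(x), 9)] = offset + w.analytic_increment(
                        i, self.temperature
                    )
            if n < len(wins) - 1:
                j = int(np.flatnonzero(np.round(w.xi - wins[n + 1].xi_ref, 9) == 0)[0])
                offset += w.analytic_increment(j, self.temperature)
        xi = np.array(sorted(values))
        profile = FreeEnergyProfile(
            xi=xi, delta_a=np.array([values[x] for x in xi]), direction="exact"
        ).rezero()
        try:
            profile.xi_R, profile.xi_TS, profile.barrier = locate_barrier(profile)
        except ValueError:
            pass
        return profile


def gen_windows(
    spec: WindowGeneratorSpec, seed: int = 0
) -> tuple[list[Window], FreeEnergyProfile]:
    """Draw per-frame ΔU samples for every window grid point.

    Samples are independent Gaussians (or symmetric two-Gaussian mixtures)
    across grid points and frames; the reference point carries exactly zero
    ΔU.  Returns the windows together with the analytic profile of the
    generating distributions.
    """
    rng = np.random.default_rng(seed)
    windows = []
    for n, w in enumerate(spec.windows):
        u = np.empty((w.xi.size, spec.frames))
        for i in range(w.xi.size):
            du = rng.normal(w.means[i], w.sigmas[i], size=spec.frames)
            if w.mixture_delta:
                sign = rng.choice([-1.0, 1.0], size=spec.frames)
                du = du + sign * w.mixture_delta
            if w.xi[i] == w.xi_ref:
                du = np.zeros(spec.frames)
            u[i] = du  # stored as U with U(ξref) ≡ 0 per frame
        windows.append(Window(index=n + 1, xi_ref=w.xi_ref, xi=w.xi, u=u))
    return windows, spec.analytic_profile()


@dataclass(frozen=True)
class EscapeGeneratorSpec:
    """First-passage escape experiment: exponential crossing times.

    Defaults emulate the dissociation experiment the estimators were built
    for: 70 trajectories of 500 ps at 1 ps resolution, escape over a 1.2 nm
    cutoff.  Crossing times are drawn directly from the exponential law —
    this generator tests the survival estimator, not barrier physics.
    """

    n_trajectories: int = 70
    length: float = 500.0  # ps
    dt: float = 1.0  # ps
    rate: float = 0.0056  # ps⁻¹
    cutoff: float = 1.2  # nm
    bound_range: tuple = (0.2, 1.15)
    escaped_range: tuple = (1.25, 3.0)

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if self.n_trajectories < 1 or self.length <= 0 or self.dt <= 0:
            raise ValueError("invalid ensemble geometry")
        if not (self.bound_range[1] <= self.cutoff <= self.escaped_range[0]):
            raise ValueError("emission ranges must be disjoint around the cutoff")


def gen_escape_ensemble(
    spec: EscapeGeneratorSpec, seed: int = 0
) -> list[DistanceTrajectory]:
    """Ensemble of distance trajectories with exponential first crossings."""
    if spec.rate > 0 and spec.dt > 1.0 / spec.rate:
        logger.warning(
            "time step %.3g ps exceeds the mean escape time %.3g ps: "
            "the discretized first-crossing times will be biased",
            spec.dt, 1.0 / spec.rate,
        )
    rng = np.random.default_rng(seed)
    n_steps = int(round(spec.length / spec.dt))
    times = np.arange(n_steps + 1) * spec.dt
    if spec.rate > 0:
        t_cross = rng.exponential(1.0 / spec.rate, size=spec.n_trajectories)
    else:
        t_cross = np.full(spec.n_trajectories, np.inf)
    trajectories = []
    for k in range(spec.n_trajectories):
        r = rng.uniform(*spec.bound_range, size=n_steps + 1)
        # first recorded crossing: first grid time >= the continuous crossing
        idx = int(np.ceil(t_cross[k] / spec.dt)) if np.isfinite(t_cross[k]) else None
        if idx is not None and idx <= n_steps:
            r[idx:] = rng.uniform(*spec.escaped_range, size=n_steps + 1 - idx)
        trajectories.append(
            DistanceTrajectory(times=times, distances=r, label=f"escape-{k}")
        )
    return trajectories


@dataclass(frozen=True)
class PairEquilibriumSpec:
    """Overdamped radial Brownian dynamics of a reactant pair.

    The pair diffuses in a radial potential W(r) — a smooth square well of
    ``well_depth`` kcal/mol out to ``well_edge`` nm — inside a reflecting
    sphere of ``outer_radius``.  The stationary density is
    p(r) ∝ r² exp(−βW(r)): a bound population plus the free quadratic tail.
    """

    well_depth: float = 3.0  # kcal/mol
    well_edge: float = 1.2  # nm
    smoothing_width: float = 0.02  # nm
    outer_radius: float = 3.0  # nm
    diffusion: float = 5e-3  # nm²/ps
    dt: float = 0.01  # ps
    n_steps: int = 500_000
    r_start: float = 1.0  # nm
    temperature: float = 300.0

    def __post_init__(self):
        if not self.well_edge < self.outer_radius:
            raise ValueError("well edge must lie inside the outer radius")
        if self.diffusion <= 0 or self.dt <= 0 or self.n_steps < 1:
            raise ValueError("invalid dynamics parameters")

    def potential(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return -self.well_depth * 0.5 * (
            1.0 - np.tanh((r - self.well_edge) / self.smoothing_width)
        )

    def force(self, r: np.ndarray) -> np.ndarray:
        """−dW/dr (kcal/mol/nm)."""
        r = np.asarray(r, dtype=float)
        sech2 = 1.0 / np.cosh((r - self.well_edge) / self.smoothing_width) ** 2
        return -self.well_depth * 0.5 * sech2 / self.smoothing_width

    def stationary_density(self, r: np.ndarray) -> np.ndarray:
        """Unnormalized stationary p(r) ∝ r² exp(−βW(r))."""
        b = beta_of(self.temperature)
        r = np.asarray(r, dtype=float)
        return r**2 * np.exp(-b * self.potential(r))

    def stationary_cdf(self, r_grid: np.ndarray) -> np.ndarray:
        """Normalized stationary CDF on a grid (trapezoidal)."""
        p = self.stationary_density(r_grid)
        cdf = np.concatenate(
            [[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(r_grid))]
        )
        return cdf / cdf[-1]

    def bound_fraction(self) -> float:
        """Equilibrium probability of r ≤ well_edge (partition integral)."""
        grid = np.linspace(1e-6, self.outer_radius, 20001)
        p = self.stationary_density(grid)
        total = np.trapezoid(p, grid)
        inside = grid <= self.well_edge
        return float(np.trapezoid(p[inside], grid[inside]) / total)


def gen_pair_equilibrium(
    spec: PairEquilibriumSpec, seed: int = 0
) -> DistanceTrajectory:
    """Euler–Maruyama integration of the radial overdamped Langevin equation.

    dr = D(βF(r) + 2/r) dt + √(2D dt) η, with F = −dW/dr and the 2/r term
    the entropic contribution of the shrinking shell volume; reflecting
    boundaries at the outer radius and near the origin.
    """
    b = beta_of(spec.temperature)
    drift_scale = spec.diffusion * b * spec.well_depth * 0.5 / spec.smoothing_width
    if drift_scale * spec.dt > 0.5 * spec.smoothing_width:
        logger.warning(
            "time step %.3g ps too large for the well stiffness: drift per "
            "step %.3g nm exceeds half the smoothing width",
            spec.dt, drift_scale * spec.dt,
        )
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, math.sqrt(2.0 * spec.diffusion * spec.dt), size=spec.n_steps)
    r = np.empty(spec.n_steps + 1)
    r[0] = spec.r_start
    d, dt = spec.diffusion, spec.dt
    r_min = 1e-3
    x = spec.r_start
    # scalar inner loop: the force is inlined for speed
    half_depth, w, edge, outer = (
        spec.well_depth * 0.5, spec.smoothing_width, spec.well_edge, spec.outer_radius
    )
    for i in range(spec.n_steps):
        sech2 = 1.0 / math.cosh((x - edge) / w) ** 2
        force = -half_depth * sech2 / w  # −dW/dr
        x = x + d * (b * force + 2.0 / x) * dt + noise[i]
        if x > outer:
            x = 2.0 * outer - x
        if x < r_min:
            x = 2.0 * r_min - x
        r[i + 1] = x
    times = np.arange(spec.n_steps + 1) * dt
    return DistanceTrajectory(times=times, distances=r, label="pair-equilibrium")


def gen_msd_tracks(
    D: float, step: float, n_steps: int, n_tracks: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Free 3-D Brownian squared-displacement tracks.

    Gaussian increments with variance 2·D·step per axis; returns
    ``(times, sq_disp)`` with ``sq_disp`` of shape (n_tracks, n_steps+1).
    The ensemble-mean MSD has slope 6D.
    """
    if D < 0:
        raise ValueError("diffusion coefficient must be non-negative")
    if step <= 0 or n_steps < 1 or n_tracks < 1:
        raise ValueError("invalid track geometry")
    rng = np.random.default_rng(seed)
    inc = rng.normal(0.0, math.sqrt(2.0 * D * step), size=(n_tracks, n_steps, 3))
    pos = np.cumsum(inc, axis=1)
    sq = np.concatenate(
        [np.zeros((n_tracks, 1)), np.sum(pos**2, axis=2)], axis=1
    )
    times = np.arange(n_steps + 1) * step
    return times, sq


def gen_point_charge_bath(
    n_charges: int,
    box: float,
    magnitude: float = 1.0,
    n_frames: int = 1,
    seed: int = 0,
    exclusion_radius: float = 0.3,
    dt: float = 1.0,
) -> list[EnvironmentSnapshot]:
    """Neutral point-charge snapshots for embedding tests.

    ``n_charges`` (even; half +magnitude, half −magnitude) are placed
    uniformly in a cube of side ``box`` centred at the origin, excluding a
    sphere of ``exclusion_radius`` around the quantum centre.
    """
    if n_charges < 0 or n_charges % 2 != 0:
        raise ValueError("n_charges must be an even non-negative count (± pairing)")
    rng = np.random.default_rng(seed)
    snapshots = []
    for f in range(n_frames):
        pts = np.empty((n_charges, 3))
        k = 0
        while k < n_charges:
            cand = rng.uniform(-box / 2, box / 2, size=(max(n_charges, 8), 3))
            keep = cand[np.linalg.norm(cand, axis=1) > exclusion_radius]
            take = min(keep.shape[0], n_charges - k)
            pts[k : k + take] = keep[:take]
            k += take
        charges = np.concatenate(
            [np.full(n_charges // 2, magnitude), np.full(n_charges // 2, -magnitude)]
        )
        snapshots.append(
            EnvironmentSnapshot(positions=pts, charges=charges, time=f * dt)
        )
    return snapshots
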